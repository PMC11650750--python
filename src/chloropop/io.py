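"""Readers and writers for the pipeline's plain-text formats.

Formats: pileup TSV (``colony gene pos ref nA nC nG nT nN``), FASTA for
references/haplotypes/consensus (consensus record ids are
``colonyID|geneID``), colony and transplant CSV tables, a GenAlEx-style
haplotype table, panel specification tables (``site_name,base,profile``)
and newick trees. All coordinates are 1-based and inclusive.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from chloropop.genotyping import (
    ConsensusSequence,
    GeneReference,
    PILEUP_COLUMNS,
    PileupColumn,
    frame_to_pileups,
    pileups_to_frame,
)
from chloropop.popgen import ColonyRecord
from chloropop.profiles import DiagnosticPanel, HaplotypeTree, PanelSite
from chloropop.transplant import TransplantRecord

DEFAULT_HAPLOTYPE_CODE_MAP = {1: "U1", 2: "U2", 3: "U3", 4: "L", 5: "O"}


class SchemaError(ValueError):
    """A file does not match the documented column schema."""


class DataError(ValueError):
    """A file matches the schema but contains invalid values."""


# ---------------------------------------------------------------- pileups


def read_pileup_frame(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"colony": str, "gene": str,
                                            "ref": str})
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing pileup columns {sorted(missing)}")
    problems = []
    pos_bad = df.index[df["pos"] < 1]
    problems += [f"line {i + 2}: pos must be >= 1" for i in pos_bad]
    for col in ("nA", "nC", "nG", "nT", "nN"):
        bad = df.index[df[col] < 0]
        problems += [f"line {i + 2}: negative count in {col}" for i in bad]
    bad_ref = df.index[~df["ref"].isin(list("ACGT"))]
    problems += [f"line {i + 2}: ref base not in ACGT" for i in bad_ref]
    if problems:
        raise DataError(f"{path}: " + "; ".join(problems[:20]))
    return df


def read_pileup_table(path) -> list[PileupColumn]:
    return frame_to_pileups(read_pileup_frame(path))


def write_pileup_table(pileups, path) -> None:
    frame = (
        pileups if isinstance(pileups, pd.DataFrame) else pileups_to_frame(pileups)
    )
    frame.to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------ FASTA


def write_reference_fasta(references: Sequence[GeneReference], path) -> None:
    records = [
        SeqRecord(Seq(r.sequence), id=r.gene_id, description="")
        for r in references
    ]
    SeqIO.write(records, path, "fasta")


def read_reference_fasta(path) -> list[GeneReference]:
    return [
        GeneReference(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(path, "fasta")
    ]


def write_consensus_fasta(consensus: Sequence[ConsensusSequence], path) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=f"{c.colony_id}|{c.gene_id}", description="")
        for c in consensus
    ]
    SeqIO.write(records, path, "fasta")


def read_consensus_fasta(path) -> list[ConsensusSequence]:
    out = []
    for rec in SeqIO.parse(path, "fasta"):
        colony, _, gene = rec.id.partition("|")
        if not gene:
            raise SchemaError(f"{path}: record id {rec.id!r} is not colony|gene")
        out.append(
            ConsensusSequence(
                colony_id=colony,
                gene_id=gene,
                sequence=str(rec.seq).upper(),
                mean_depth=float("nan"),
                n_called=sum(1 for b in str(rec.seq).upper() if b != "N"),
            )
        )
    return out


def write_haplotype_fasta(haplotypes: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=label, description="")
        for label, seq in haplotypes.items()
    ]
    SeqIO.write(records, path, "fasta")


# ----------------------------------------------------------- colony table

COLONY_COLUMNS = [
    "colony", "reef", "region", "profile", "host_lineage",
    "x_km", "y_km", "secondary_profile", "minor_fraction",
]


def write_colony_table(colonies: Sequence[ColonyRecord], path) -> None:
    df = pd.DataFrame(
        [
            (c.colony_id, c.reef_id, c.region_id, c.profile, c.host_lineage,
             c.x_km, c.y_km, c.secondary_profile, c.minor_fraction)
            for c in colonies
        ],
        columns=COLONY_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_colony_table(path) -> list[ColonyRecord]:
    df = pd.read_csv(path, dtype={"colony": str, "reef": str, "region": str})
    missing = {"colony", "reef", "region", "profile"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing colony columns {sorted(missing)}")
    out = []
    for r in df.itertuples(index=False):
        out.append(
            ColonyRecord(
                colony_id=str(r.colony),
                reef_id=str(r.reef),
                region_id=str(r.region),
                profile=str(r.profile),
                host_lineage=(None if pd.isna(getattr(r, "host_lineage", None))
                              else str(r.host_lineage)),
                x_km=(None if pd.isna(getattr(r, "x_km", None))
                      else float(r.x_km)),
                y_km=(None if pd.isna(getattr(r, "y_km", None))
                      else float(r.y_km)),
                secondary_profile=(
                    None
                    if pd.isna(getattr(r, "secondary_profile", None))
                    else str(r.secondary_profile)
                ),
                minor_fraction=(
                    0.0
                    if pd.isna(getattr(r, "minor_fraction", None))
                    else float(r.minor_fraction)
                ),
            )
        )
    return out


# -------------------------------------------------------- transplant table

TRANSPLANT_COLUMNS = [
    "sample_id", "native_reef", "native_region", "native_profile",
    "transplant_reef", "panel", "row", "col", "survived", "post_profile",
]


def write_transplant_table(records: Sequence[TransplantRecord], path) -> None:
    df = pd.DataFrame(
        [
            (r.sample_id, r.native_reef, r.native_region, r.native_profile,
             r.transplant_reef, r.panel_id, r.row, r.col, int(r.survived),
             r.post_profile)
            for r in records
        ],
        columns=TRANSPLANT_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_transplant_table(path) -> list[TransplantRecord]:
    df = pd.read_csv(
        path,
        dtype={"sample_id": str, "native_reef": str, "transplant_reef": str,
               "panel": str},
    )
    missing = {"sample_id", "native_reef", "native_profile", "transplant_reef",
               "survived"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing transplant columns {sorted(missing)}")
    out = []
    for r in df.itertuples(index=False):
        post = getattr(r, "post_profile", None)
        out.append(
            TransplantRecord(
                sample_id=str(r.sample_id),
                native_reef=str(r.native_reef),
                native_region=(None if pd.isna(getattr(r, "native_region", None))
                               else str(r.native_region)),
                native_profile=str(r.native_profile),
                transplant_reef=str(r.transplant_reef),
                panel_id=str(getattr(r, "panel", "")),
                row=int(getattr(r, "row", 0)),
                col=int(getattr(r, "col", 0)),
                survived=bool(int(r.survived)),
                post_profile=None if pd.isna(post) else str(post),
            )
        )
    return out


# ------------------------------------------------------------------ panel


def write_panel_table(panel: DiagnosticPanel, path) -> None:
    rows = [
        (s.name, panel.profile_bases[pid][s.name], pid)
        for pid in panel.profile_ids
        for s in panel.sites
    ]
    pd.DataFrame(rows, columns=["site_name", "base", "profile"]).to_csv(
        path, index=False
    )


def read_panel_table(path) -> DiagnosticPanel:
    df = pd.read_csv(path)
    missing = {"site_name", "base", "profile"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing panel columns {sorted(missing)}")
    profile_bases: dict[str, dict[str, str]] = {}
    for r in df.itertuples(index=False):
        profile_bases.setdefault(str(r.profile), {})[str(r.site_name)] = str(r.base)
    site_names = sorted(
        {str(n) for n in df["site_name"]},
        key=lambda n: (PanelSite.from_name(n).gene_id,
                       PanelSite.from_name(n).position),
    )
    for pid, bases in profile_bases.items():
        if set(bases) != set(site_names):
            raise DataError(f"{path}: profile {pid!r} missing some panel sites")
    return DiagnosticPanel(
        sites=tuple(PanelSite.from_name(n) for n in site_names),
        profile_bases=profile_bases,
    )


# ---------------------------------------------------------------- GenAlEx


def read_genalex_haplotypes(
    path, code_map: Mapping[int, str] | None = None
) -> list[ColonyRecord]:
    """Read a GenAlEx-style haplotype table.

    Layout (comma-separated): a parameter row ``n_loci,n_samples,n_pops,
    size1,size2,...``; a title row; a header row ``Sample,Pop,Haplotype
    [,Region]``; then one row per sample with an integer haplotype code.
    Codes map to profile labels through ``code_map`` (default
    1->U1 ... 5->O). Without a Region column the population doubles as the
    region.
    """
    code_map = dict(code_map or DEFAULT_HAPLOTYPE_CODE_MAP)
    lines = Path(path).read_text().splitlines()
    if len(lines) < 4:
        raise SchemaError(f"{path}: too short for a GenAlEx haplotype file")
    params = [p.strip() for p in lines[0].split(",") if p.strip() != ""]
    try:
        n_loci, n_samples, n_pops = (int(x) for x in params[:3])
        sizes = [int(x) for x in params[3 : 3 + n_pops]]
    except (ValueError, IndexError) as exc:
        raise SchemaError(f"{path}: malformed parameter row") from exc
    header = [h.strip().lower() for h in lines[2].split(",")]
    if header[:3] != ["sample", "pop", "haplotype"]:
        raise SchemaError(
            f"{path}: expected header Sample,Pop,Haplotype[,Region]"
        )
    has_region = len(header) > 3 and header[3] == "region"
    rows = [ln for ln in lines[3:] if ln.strip()]
    if len(rows) != n_samples:
        raise SchemaError(
            f"{path}: declared {n_samples} samples but found {len(rows)} rows"
        )
    out = []
    pop_counts: dict[str, int] = {}
    for ln in rows:
        cells = [c.strip() for c in ln.split(",")]
        sample, pop, code_s = cells[:3]
        try:
            code = int(code_s)
        except ValueError as exc:
            raise DataError(
                f"{path}: non-integer haplotype code {code_s!r}"
            ) from exc
        if code not in code_map:
            raise DataError(f"{path}: haplotype code {code} not in code map")
        region = cells[3] if has_region and len(cells) > 3 else pop
        pop_counts[pop] = pop_counts.get(pop, 0) + 1
        out.append(
            ColonyRecord(
                colony_id=sample, reef_id=pop, region_id=region,
                profile=code_map[code],
            )
        )
    if len(pop_counts) != n_pops or list(pop_counts.values()) != sizes:
        raise SchemaError(
            f"{path}: declared population sizes {sizes} inconsistent with "
            f"rows {dict(pop_counts)}"
        )
    return out


def write_genalex_haplotypes(
    colonies: Sequence[ColonyRecord],
    path,
    code_map: Mapping[int, str] | None = None,
    title: str = "chloropop haplotype export",
) -> None:
    code_map = dict(code_map or DEFAULT_HAPLOTYPE_CODE_MAP)
    label_to_code = {v: k for k, v in code_map.items()}
    pops: dict[str, list[ColonyRecord]] = {}
    for c in colonies:
        pops.setdefault(c.reef_id, []).append(c)
    pop_names = list(pops)
    lines = [
        ",".join(
            ["1", str(len(colonies)), str(len(pop_names))]
            + [str(len(pops[p])) for p in pop_names]
        ),
        title,
        "Sample,Pop,Haplotype,Region",
    ]
    for p in pop_names:
        for c in pops[p]:
            if c.profile not in label_to_code:
                raise DataError(f"profile {c.profile!r} has no haplotype code")
            lines.append(
                f"{c.colony_id},{c.reef_id},{label_to_code[c.profile]},"
                f"{c.region_id}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------- newick


def write_newick(tree: HaplotypeTree, path) -> None:
    try:
        Path(path).write_text(tree.to_newick() + "\n")
    except OSError as exc:
        raise OSError(f"failed writing newick to {path}: {exc}") from exc


# ------------------------------------------------------------- run config


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (one global seed)."""

    seed: int
    pileups: str | None = None
    reference: str | None = None
    panel: str | None = None
    colonies: str | None = None
    transplants: str | None = None
    out_dir: str = "chloropop_run"
    min_depth: int = 5
    min_minor_count: int = 2
    min_minor_fraction: float = 0.10
    distance_mode: str = "mismatch01"
    n_permutations: int = 999
    bin_max_km: float = 88.0
    clamp_negative_variance: bool = False
    neighbor_connectivity: int = 8

    @staticmethod
    def load(path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
        if "seed" not in raw:
            raise SchemaError(f"{path}: config must set a seed")
        cfg = RunConfig(**raw)
        for name in ("pileups", "reference", "panel", "colonies", "transplants"):
            p = getattr(cfg, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config {name} path does not exist: {p}")
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def write_manifest(out_dir, config: Mapping, inputs: Sequence[str] = ()) -> Path:
    """Record config, package version and input checksums for replay."""
    from chloropop import __version__

    checksums = {}
    for p in inputs:
        path = Path(p)
        if path.exists():
            checksums[str(p)] = hashlib.md5(path.read_bytes()).hexdigest()
    manifest = {
        "version": __version__,
        "config": dict(config),
        "input_md5": checksums,
    }
    out = Path(out_dir) / "manifest.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
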