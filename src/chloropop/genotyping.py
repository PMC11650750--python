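"""Haploid consensus calling and SNP discovery from per-site pileups.

Chloroplast minicircle genes are effectively haploid within a colony's
dominant symbiont, so genotyping reduces to majority-base calling per site
against a colinear reference (no indels are modelled). All coordinates are
1-based and inclusive; SNP sites are named ``gene.position`` (e.g.
``atpA.44``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
MISSING = "N"

PILEUP_COLUMNS = ["colony", "gene", "pos", "ref", "nA", "nC", "nG", "nT", "nN"]


@dataclass(frozen=True)
class GeneReference:
    """One reference gene: an id and a nucleotide sequence (A/C/G/T only)."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty reference sequence for {self.gene_id!r}")
        bad = set(self.sequence) - set(BASES)
        if bad:
            raise ValueError(
                f"reference {self.gene_id!r} contains non-ACGT characters: {sorted(bad)}"
            )

    @property
    def length_nt(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PileupColumn:
    """Per-site base counts for one gene position in one colony."""

    colony_id: str
    gene_id: str
    position: int  # 1-based
    ref_base: str
    nA: int = 0
    nC: int = 0
    nG: int = 0
    nT: int = 0
    nN: int = 0

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"positions are 1-based; got {self.position}")
        for name in ("nA", "nC", "nG", "nT", "nN"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative count {name}={getattr(self, name)}")
        if self.ref_base not in BASES:
            raise ValueError(f"ref_base must be one of {BASES}; got {self.ref_base!r}")

    @property
    def depth(self) -> int:
        """Usable depth: A+C+G+T counts (N reads are not informative)."""
        return self.nA + self.nC + self.nG + self.nT

    @property
    def counts(self) -> dict[str, int]:
        return {"A": self.nA, "C": self.nC, "G": self.nG, "T": self.nT, "N": self.nN}


@dataclass(frozen=True)
class ConsensusSequence:
    """Haploid consensus for one gene in one colony, colinear with the reference."""

    colony_id: str
    gene_id: str
    sequence: str
    mean_depth: float
    n_called: int


class SnpSite(NamedTuple):
    gene_id: str
    position: int
    ref_base: str | None
    alleles: tuple[str, ...]

    @property
    def name(self) -> str:
        return f"{self.gene_id}.{self.position}"


@dataclass
class SnpTable:
    """Variable sites across colonies and the colony x site genotype matrix.

    ``genotypes`` is a DataFrame indexed by colony id with one column per
    site (named ``gene.position``); uncalled genotypes are ``N``.
    """

    sites: list[SnpSite]
    genotypes: pd.DataFrame

    @property
    def site_names(self) -> list[str]:
        return [s.name for s in self.sites]

    @property
    def n_snps(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class GeneSummary:
    gene_id: str
    aa_length: int | None
    n_snps: int
    avg_snps_per_genome: float
    pi: float


def pileups_to_frame(pileups: Iterable[PileupColumn]) -> pd.DataFrame:
    """Convert PileupColumn records to the canonical tabular layout."""
    rows = [
        (p.colony_id, p.gene_id, p.position, p.ref_base, p.nA, p.nC, p.nG, p.nT, p.nN)
        for p in pileups
    ]
    return pd.DataFrame(rows, columns=PILEUP_COLUMNS)


def frame_to_pileups(frame: pd.DataFrame) -> list[PileupColumn]:
    return [
        PileupColumn(
            colony_id=str(r.colony),
            gene_id=str(r.gene),
            position=int(r.pos),
            ref_base=str(r.ref),
            nA=int(r.nA),
            nC=int(r.nC),
            nG=int(r.nG),
            nT=int(r.nT),
            nN=int(r.nN),
        )
        for r in frame.itertuples(index=False)
    ]


def _as_frame(pileups) -> pd.DataFrame:
    if isinstance(pileups, pd.DataFrame):
        missing = set(PILEUP_COLUMNS) - set(pileups.columns)
        if missing:
            raise ValueError(f"pileup frame missing columns: {sorted(missing)}")
        return pileups
    return pileups_to_frame(pileups)


def call_consensus(
    pileups,
    reference: Sequence[GeneReference],
    min_depth: int = 5,
) -> list[ConsensusSequence]:
    """Call a haploid consensus per (colony, gene) by majority base.

    At each site with depth >= ``min_depth`` the base with the highest count
    wins; ties including the reference base resolve to the reference (the
    prior of a reference-based caller), other ties resolve in fixed base
    order A<C<G<T. Sites below ``min_depth`` or without pileup rows are N.

    Raises ``ValueError`` for pileup positions beyond the reference length.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    frame = _as_frame(pileups)
    ref_by_gene = {g.gene_id: g for g in reference}

    out: list[ConsensusSequence] = []
    for (colony, gene), grp in frame.groupby(["colony", "gene"], sort=True):
        if gene not in ref_by_gene:
            raise KeyError(f"gene {gene!r} not present in the reference set")
        gref = ref_by_gene[gene]
        pos = grp["pos"].to_numpy(dtype=np.int64)
        if (pos < 1).any() or (pos > gref.length_nt).any():
            raise ValueError(
                f"pileup position outside reference bounds for {gene!r} "
                f"(length {gref.length_nt})"
            )
        counts = grp[["nA", "nC", "nG", "nT"]].to_numpy(dtype=np.int64)
        depth = counts.sum(axis=1)

        seq = np.full(gref.length_nt, MISSING, dtype="U1")
        maxv = counts.max(axis=1)
        winners = counts == maxv[:, None]
        ref_idx = np.array([_BASE_INDEX[b] for b in grp["ref"]], dtype=np.int64)
        ref_wins = winners[np.arange(len(grp)), ref_idx]
        # default winner: first base (A<C<G<T order) achieving the max
        win_idx = winners.argmax(axis=1)
        win_idx[ref_wins] = ref_idx[ref_wins]
        called = depth >= min_depth
        base_arr = np.array(BASES, dtype="U1")
        seq[pos[called] - 1] = base_arr[win_idx[called]]

        out.append(
            ConsensusSequence(
                colony_id=str(colony),
                gene_id=str(gene),
                sequence="".join(seq),
                mean_depth=float(depth.mean()) if len(depth) else 0.0,
                n_called=int(called.sum()),
            )
        )
    return out


def _consensus_matrix(
    consensus: Sequence[ConsensusSequence], gene: str
) -> tuple[list[str], np.ndarray]:
    """Colony labels and a (colonies x sites) byte matrix for one gene."""
    recs = sorted(
        (c for c in consensus if c.gene_id == gene), key=lambda c: c.colony_id
    )
    lengths = {len(c.sequence) for c in recs}
    if len(lengths) > 1:
        raise ValueError(f"inconsistent consensus lengths for gene {gene!r}: {lengths}")
    mat = np.frombuffer(
        "".join(c.sequence for c in recs).encode(), dtype="S1"
    ).reshape(len(recs), -1)
    return [c.colony_id for c in recs], mat


def discover_snps(
    consensus: Sequence[ConsensusSequence],
    reference: Sequence[GeneReference] | None = None,
) -> SnpTable:
    """Find all sites with >= 2 distinct non-N alleles across colonies.

    A site where all but one colony is N is not variable. Genotypes for
    uncalled colonies are reported as N. If a reference is supplied its base
    is recorded per site; otherwise the site's majority allele stands in.
    """
    genes = sorted({c.gene_id for c in consensus})
    colonies = sorted({c.colony_id for c in consensus})
    if len(colonies) < 2:
        raise ValueError("SNP discovery needs >= 2 colonies")
    ref_by_gene = {g.gene_id: g for g in reference} if reference else {}

    sites: list[SnpSite] = []
    columns: dict[str, pd.Series] = {}
    for gene in genes:
        labels, mat = _consensus_matrix(consensus, gene)
        if labels != colonies:
            raise ValueError(
                f"gene {gene!r} is missing consensus for some colonies"
            )
        non_missing = mat != b"N"
        for j in range(mat.shape[1]):
            col = mat[:, j]
            alleles = sorted(set(col[non_missing[:, j]].tobytes().decode()))
            if len(alleles) < 2:
                continue
            if gene in ref_by_gene:
                ref_base = ref_by_gene[gene].sequence[j]
            else:
                decoded = col[non_missing[:, j]].tobytes().decode()
                ref_base = max(sorted(set(decoded)), key=decoded.count)
            site = SnpSite(gene, j + 1, ref_base, tuple(alleles))
            sites.append(site)
            columns[site.name] = pd.Series(
                [c.decode() for c in col], index=colonies
            )
    genotypes = pd.DataFrame(columns, index=colonies)
    return SnpTable(sites=sites, genotypes=genotypes)


def nucleotide_diversity(sequences: Sequence[str]) -> float:
    """Average pairwise difference per site with pairwise deletion of N.

    For every colony pair, differences are counted only at sites where both
    members are non-N and divided by the number of such sites; pi is the
    mean over all C(n,2) pairs. Pairs with zero comparable sites are
    excluded.
    """
    n = len(sequences)
    if n < 2:
        raise ValueError("pi needs >= 2 sequences")
    lengths = {len(s) for s in sequences}
    if len(lengths) > 1:
        raise ValueError("sequences must have equal length")
    mat = np.frombuffer("".join(sequences).encode(), dtype="S1").reshape(n, -1)
    ok = mat != b"N"
    vals = []
    for i, j in itertools.combinations(range(n), 2):
        both = ok[i] & ok[j]
        m = int(both.sum())
        if m == 0:
            continue
        vals.append(int(((mat[i] != mat[j]) & both).sum()) / m)
    if not vals:
        raise ValueError("no colony pair has comparable (non-N) sites")
    return float(np.mean(vals))


def gene_summaries(
    consensus: Sequence[ConsensusSequence],
    snps: SnpTable,
    reference: Sequence[GeneReference],
    aa_lengths: Mapping[str, int] | None = None,
) -> list[GeneSummary]:
    """Per-gene SNP count, mean non-reference calls per colony, and pi."""
    ref_by_gene = {g.gene_id: g for g in reference}
    genes = sorted({c.gene_id for c in consensus})
    out = []
    for gene in genes:
        if gene not in ref_by_gene:
            raise KeyError(f"gene {gene!r} not present in the reference set")
        labels, mat = _consensus_matrix(consensus, gene)
        refarr = np.frombuffer(ref_by_gene[gene].sequence.encode(), dtype="S1")
        non_ref = (mat != refarr) & (mat != b"N")
        n_snps = sum(1 for s in snps.sites if s.gene_id == gene)
        out.append(
            GeneSummary(
                gene_id=gene,
                aa_length=aa_lengths.get(gene) if aa_lengths else None,
                n_snps=n_snps,
                avg_snps_per_genome=float(non_ref.sum(axis=1).mean()),
                pi=nucleotide_diversity([c.decode() for c in
                                         (row.tobytes() for row in mat)]),
            )
        )
    return out


def majority_consensus(aligned_sequences: Sequence[str]) -> str:
    """Column-wise majority consensus of equal-length aligned sequences.

    Gaps (``-``) and ``N`` (and any other non-ACGT character) are excluded
    from the vote; a column with no ACGT votes yields N. Ties break in fixed
    base order A<C<G<T.
    """
    if not aligned_sequences:
        raise ValueError("need at least one sequence")
    lengths = {len(s) for s in aligned_sequences}
    if len(lengths) > 1:
        raise ValueError(f"aligned sequences differ in length: {sorted(lengths)}")
    n = len(aligned_sequences)
    mat = np.frombuffer(
        "".join(s.upper() for s in aligned_sequences).encode(), dtype="S1"
    ).reshape(n, -1)
    counts = np.stack([(mat == b.encode()).sum(axis=0) for b in BASES])
    best = counts.argmax(axis=0)  # argmax takes the first max: A<C<G<T order
    seq = np.array(BASES, dtype="U1")[best]
    seq[counts.sum(axis=0) == 0] = MISSING
    return "".join(seq)


def concatenate_consensus(
    consensus: Sequence[ConsensusSequence],
    gene_order: Sequence[str] | None = None,
) -> tuple[dict[str, str], dict[str, int]]:
    """Concatenate per-gene consensus into one sequence per colony.

    Returns ``(colony -> concatenated sequence, gene -> 0-based offset)``.
    Gene order defaults to alphabetical, which is the fixed concatenation
    order used throughout the package.
    """
    genes = sorted({c.gene_id for c in consensus})
    if gene_order is not None:
        if set(gene_order) != set(genes):
            raise ValueError("gene_order must cover exactly the genes present")
        genes = list(gene_order)
    by_colony: dict[str, dict[str, str]] = {}
    for c in consensus:
        by_colony.setdefault(c.colony_id, {})[c.gene_id] = c.sequence
    offsets: dict[str, int] = {}
    off = 0
    lengths: dict[str, int] = {}
    for g in genes:
        lens = {len(d[g]) for d in by_colony.values() if g in d}
        if len(lens) != 1:
            raise ValueError(f"gene {g!r} missing or length-inconsistent")
        offsets[g] = off
        lengths[g] = lens.pop()
        off += lengths[g]
    concat = {}
    for colony, d in sorted(by_colony.items()):
        if set(d) != set(genes):
            raise ValueError(f"colony {colony!r} lacks some genes")
        concat[colony] = "".join(d[g] for g in genes)
    return concat, offsets
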