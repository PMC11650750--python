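"""Synthetic study generator: references, profile haplotypes, reef mosaics,
pileups and a common-garden transplant experiment.

The generator reproduces the statistical structure the downstream analysis
assumes: 11 chloroplast protein-coding genes (~13.8 kb concatenated), five
ingroup profile haplotypes (U1/U2/U3/L) differing at a 10-site diagnostic
SNP panel, divergent outgroup haplotypes (O1/O2) carrying a few tens of
extra substitutions, reef mosaics with region-structured profile
frequencies, per-site Poisson read depth around 35x with uniform
sequencing error, a configurable fraction of mixed-profile colonies, and a
two-stage transplant survival process with a low (~13%) switch rate.
All draws are reproducible from ``SimulationConfig.seed``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from chloropop.genotyping import BASES, GeneReference, PileupColumn, PILEUP_COLUMNS
from chloropop.popgen import ColonyRecord
from chloropop.profiles import DiagnosticPanel, PanelSite
from chloropop.transplant import TransplantRecord, UNCALLED

# amino-acid lengths of the 11 chloroplast genes; nucleotide length is aa x 3
GENE_AA_LENGTHS: dict[str, int] = {
    "atpA": 508,
    "atpB": 481,
    "petB": 218,
    "petD": 160,
    "psaA": 750,
    "psaB": 735,
    "psbA": 350,
    "psbB": 508,
    "psbC": 461,
    "psbD": 353,
    "psbE": 83,
}
GENE_ORDER: tuple[str, ...] = tuple(sorted(GENE_AA_LENGTHS))  # alphabetical

# the five U/L-splitting sites plus the extra U-subdividing and outgroup sites
_UL_SITES = ("atpA.44", "atpB.451", "atpB.578", "psaA.1765", "psaB.1690")
DEFAULT_PANEL_SITE_NAMES: tuple[str, ...] = (
    "atpA.44", "atpA.129", "atpA.187", "atpB.451", "atpB.578",
    "atpB.648", "psaA.1765", "psaB.1690", "psaB.1774", "psbC.489",
)
# profile -> panel sites at which that profile carries the alternate base
DEFAULT_PANEL_SPEC: dict[str, frozenset[str]] = {
    "U1": frozenset(_UL_SITES),
    "U2": frozenset(_UL_SITES) | {"atpA.129"},
    "U3": frozenset(_UL_SITES) | {"atpA.187"},
    "L": frozenset(),
    "O1": frozenset({"atpB.648", "psaB.1774", "psbC.489"}),
    "O2": frozenset({"psaB.1774", "psbC.489"}),
}
DEFAULT_OUTGROUP_PROFILES: tuple[str, ...] = ("O1", "O2")

# printed per-reef one-year survival of immediate survivors at the five
# common-garden sites, in deployment order
DEFAULT_SITE_SURVIVAL: tuple[float, ...] = (0.48, 0.42, 0.09, 0.16, 0.21)


@dataclass(frozen=True)
class ProfileDefinition:
    """A profile haplotype as substitutions relative to the reference."""

    profile_id: str
    substitutions: tuple[tuple[str, int, str], ...]  # (gene, 1-based pos, alt)

    def __post_init__(self) -> None:
        keys = [(g, p) for g, p, _ in self.substitutions]
        if len(set(keys)) != len(keys):
            raise ValueError(
                f"profile {self.profile_id!r} has duplicate substitution sites"
            )


@dataclass(frozen=True)
class Reef:
    reef_id: str
    region_id: str
    x_km: float
    y_km: float
    mean_temp: float
    sd_daily_temp: float


@dataclass
class ReefLayout:
    reefs: list[Reef]
    profile_freqs: Mapping[str, Mapping[str, float]]  # reef -> profile -> freq

    def __post_init__(self) -> None:
        ids = [r.reef_id for r in self.reefs]
        if len(set(ids)) != len(ids):
            raise ValueError("reef ids must be unique")
        for rid in ids:
            freqs = self.profile_freqs[rid]
            vals = np.array(list(freqs.values()), dtype=float)
            if (vals < 0).any():
                raise ValueError(f"negative frequency for reef {rid!r}")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"frequencies for reef {rid!r} sum to {vals.sum()}, not 1"
                )

    @property
    def reef_ids(self) -> list[str]:
        return [r.reef_id for r in self.reefs]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Defaults mirror the sequencing study being emulated: mean chloroplast
    read depth 35.4x, ~16.5% of adequately covered colonies carrying a
    second profile, a 13% dominant-profile switch rate among assayed
    transplant ramets, 80% immediate transplant survival followed by
    reef-specific one-year survival, and a post-transplant genotyping
    success rate of 91/170.
    """

    n_colonies_per_reef: int = 7
    mean_depth: float = 35.4
    fixed_depth: int | None = None  # overrides the Poisson depth model
    error_rate: float = 0.005
    mixed_fraction: float = 0.165
    mixed_minor_fraction: float = 0.3
    switch_rate: float = 0.13
    switch_local_weight: float = 0.5  # local dominant vs panel neighbour
    immediate_survival: float = 633 / 790
    site_survival: tuple[float, ...] = DEFAULT_SITE_SURVIVAL
    post_call_rate: float = 91 / 170
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "error_rate", "mixed_fraction", "mixed_minor_fraction",
            "switch_rate", "switch_local_weight", "immediate_survival",
            "post_call_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]; got {v}")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.n_colonies_per_reef < 1:
            raise ValueError("n_colonies_per_reef must be >= 1")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(BASES)[rng.integers(0, 4, size=length)])


def make_reference_and_profiles(
    panel_spec: Mapping[str, frozenset[str] | set[str]] | None = None,
    outgroup_divergence: int = 30,
    seed: int = 0,
    gene_aa_lengths: Mapping[str, int] | None = None,
    outgroup_profiles: Sequence[str] = DEFAULT_OUTGROUP_PROFILES,
) -> tuple[list[GeneReference], list[ProfileDefinition], DiagnosticPanel]:
    """Build reference genes, profile haplotypes and the diagnostic panel.

    ``panel_spec`` maps each profile to the panel sites at which it carries
    the alternate (non-reference) base; outgroup profiles additionally gain
    ``outgroup_divergence`` random substitutions outside the panel. Per-gene
    nucleotide lengths default to the 11-gene amino-acid table x 3.
    """
    if outgroup_divergence < 0:
        raise ValueError("outgroup_divergence must be >= 0")
    if panel_spec is None:
        panel_spec = DEFAULT_PANEL_SPEC
    aa = dict(gene_aa_lengths or GENE_AA_LENGTHS)
    rng = np.random.default_rng(seed)

    references = [
        GeneReference(g, _random_sequence(rng, aa[g] * 3)) for g in sorted(aa)
    ]
    lengths = {r.gene_id: r.length_nt for r in references}

    site_names = sorted(
        {s for sites in panel_spec.values() for s in sites},
        key=lambda n: (PanelSite.from_name(n).gene_id, PanelSite.from_name(n).position),
    )
    sites = [PanelSite.from_name(n) for n in site_names]
    for s in sites:
        if s.gene_id not in lengths:
            raise ValueError(f"panel site {s.name} names unknown gene")
        if not 1 <= s.position <= lengths[s.gene_id]:
            raise ValueError(
                f"panel site {s.name} outside gene bounds (length "
                f"{lengths[s.gene_id]})"
            )
    specs = {pid: frozenset(v) for pid, v in panel_spec.items()}
    for a, b in itertools.combinations(specs, 2):
        if specs[a] == specs[b] and len(specs) > 1:
            raise ValueError(f"profiles {a!r} and {b!r} have identical panel bases")

    ref_seq = {r.gene_id: r.sequence for r in references}
    # one fixed alternate base per panel site, different from the reference
    alt_base = {}
    for s in sites:
        ref_b = ref_seq[s.gene_id][s.position - 1]
        alts = [b for b in BASES if b != ref_b]
        alt_base[s.name] = alts[int(rng.integers(0, 3))]

    profile_defs = []
    panel_positions = {(s.gene_id, s.position) for s in sites}
    genes_sorted = sorted(aa)
    offsets = {}
    off = 0
    for g in genes_sorted:
        offsets[g] = off
        off += lengths[g]
    total_len = off

    for pid, carried in specs.items():
        subs = [
            (s.gene_id, s.position, alt_base[s.name])
            for s in sites
            if s.name in carried
        ]
        if pid in outgroup_profiles and outgroup_divergence > 0:
            pool = np.array(
                [
                    i
                    for i in range(total_len)
                    if _concat_to_gene(i, genes_sorted, offsets, lengths)
                    not in panel_positions
                ]
            )
            chosen = rng.choice(pool, size=outgroup_divergence, replace=False)
            for i in sorted(int(c) for c in chosen):
                g, p = _concat_to_gene(i, genes_sorted, offsets, lengths)
                ref_b = ref_seq[g][p - 1]
                alts = [b for b in BASES if b != ref_b]
                subs.append((g, p, alts[int(rng.integers(0, 3))]))
        profile_defs.append(ProfileDefinition(pid, tuple(subs)))

    profile_bases = {
        pid: {
            s.name: (alt_base[s.name] if s.name in specs[pid]
                     else ref_seq[s.gene_id][s.position - 1])
            for s in sites
        }
        for pid in specs
    }
    panel = DiagnosticPanel(sites=tuple(sites), profile_bases=profile_bases)
    return references, profile_defs, panel


def _concat_to_gene(i, genes_sorted, offsets, lengths):
    for g in reversed(genes_sorted):
        if i >= offsets[g]:
            return (g, i - offsets[g] + 1)
    raise IndexError(i)


def haplotype_sequences(
    profile: ProfileDefinition, references: Sequence[GeneReference]
) -> dict[str, str]:
    """Per-gene haplotype of a profile: reference plus its substitutions."""
    seqs = {r.gene_id: list(r.sequence) for r in references}
    for gene, pos, alt in profile.substitutions:
        if gene not in seqs:
            raise KeyError(f"substitution names unknown gene {gene!r}")
        if not 1 <= pos <= len(seqs[gene]):
            raise ValueError(f"substitution {gene}.{pos} outside gene bounds")
        seqs[gene][pos - 1] = alt
    return {g: "".join(s) for g, s in seqs.items()}


def concatenated_haplotype(
    profile: ProfileDefinition, references: Sequence[GeneReference]
) -> str:
    seqs = haplotype_sequences(profile, references)
    return "".join(seqs[g] for g in sorted(seqs))


def example_layout(
    seed: int = 0,
    profile_ids: Sequence[str] = tuple(DEFAULT_PANEL_SPEC),
) -> ReefLayout:
    """A 39-reef, 7-region archipelago mosaic with structured frequencies.

    Regions emulate a lagoon system: two northern regions where a second
    upper profile (U2) occurs, mid-lagoon regions dominated by U1, a
    forereef transect with a steep outgroup cline, and southern reefs split
    between U3- and L-dominated clusters. Coordinates span ~90 km; reef
    temperatures vary by ~1.5 degC with differing daily fluctuation.
    """
    spec = [
        # (region, n reefs, y range, base frequencies)
        ("NofEbiil", 5, (80, 90), {"U1": 0.45, "U2": 0.35, "L": 0.20}),
        ("EbiilFR", 5, (70, 80), {"U1": 0.40, "U2": 0.40, "L": 0.20}),
        ("north", 6, (55, 68), {"U1": 0.70, "L": 0.30}),
        ("west", 5, (40, 52), {"U1": 0.80, "L": 0.20}),
        ("east", 6, (35, 50), {"U1": 0.90, "L": 0.06, "O2": 0.04}),
        ("UlongFR", 5, (12, 24), None),  # outgroup cline, built below
        ("south", 7, (0, 12), None),  # U3 vs L clusters, built below
    ]
    rng = np.random.default_rng(seed)
    reefs: list[Reef] = []
    freqs: dict[str, dict[str, float]] = {}
    rid = 0
    for region, n, (y0, y1), base in spec:
        for k in range(n):
            rid += 1
            name = str(rid)
            y = y0 + (y1 - y0) * (k + 0.5) / n
            x = {"west": 5.0, "UlongFR": 8.0}.get(region, 20.0) + 6.0 * (
                rng.random() - 0.5
            )
            mean_temp = 29.0 + 0.015 * (90 - y) + 0.2 * rng.random()
            sd_daily = 0.4 + 0.008 * (90 - y) + 0.1 * rng.random()
            reefs.append(Reef(name, region, float(x), float(y),
                              round(float(mean_temp), 3), round(float(sd_daily), 3)))
            if base is not None:
                f = dict(base)
            elif region == "UlongFR":
                o = 0.05 + 0.85 * k / (n - 1)  # 5% -> 90% outgroup northward
                f = {"O1": round(o, 6), "U3": round(0.7 * (1 - o), 6),
                     "L": round(0.3 * (1 - o), 6)}
            else:  # south
                if k < 3:
                    f = {"U3": 0.70, "L": 0.20, "U1": 0.10}
                else:
                    f = {"L": 0.75, "U1": 0.15, "U3": 0.10}
            total = sum(f.values())
            f = {p: v / total for p, v in f.items() if p in profile_ids}
            freqs[name] = f
    return ReefLayout(reefs=reefs, profile_freqs=freqs)


def simulate_population(
    layout: ReefLayout,
    profiles: Sequence[ProfileDefinition],
    config: SimulationConfig,
) -> list[ColonyRecord]:
    """Draw colonies reef by reef from the layout's profile frequencies.

    A ``mixed_fraction`` subset of colonies carries a secondary profile
    (drawn from the reef's other profiles, uniformly if the reef is fixed)
    at ``mixed_minor_fraction`` relative abundance.
    """
    if not layout.reefs:
        raise ValueError("layout has no reefs")
    known = {p.profile_id for p in profiles}
    rng = np.random.default_rng(config.seed)
    lineages = np.array(["CS1", "CS2", "CS3", "CS4", "CS5"])
    lineage_p = np.array([0.12, 0.027, 0.027, 0.026, 0.80])
    out: list[ColonyRecord] = []
    cid = 0
    for reef in layout.reefs:
        fr = layout.profile_freqs[reef.reef_id]
        unknown = set(fr) - known
        if unknown:
            raise ValueError(
                f"reef {reef.reef_id!r} frequencies name unknown profiles "
                f"{sorted(unknown)}"
            )
        labels = list(fr)
        p = np.array([fr[k] for k in labels], dtype=float)
        for _ in range(config.n_colonies_per_reef):
            cid += 1
            main = labels[int(rng.choice(len(labels), p=p))]
            secondary = None
            minor = 0.0
            if rng.random() < config.mixed_fraction:
                others = [x for x in labels if x != main and fr[x] > 0]
                if not others:
                    others = sorted(known - {main})
                weights = np.array([fr.get(x, 0.0) for x in others])
                if weights.sum() == 0:
                    weights = np.ones(len(others))
                weights = weights / weights.sum()
                secondary = others[int(rng.choice(len(others), p=weights))]
                minor = config.mixed_minor_fraction
            out.append(
                ColonyRecord(
                    colony_id=str(cid),
                    reef_id=reef.reef_id,
                    region_id=reef.region_id,
                    profile=main,
                    host_lineage=str(lineages[int(rng.choice(5, p=lineage_p))]),
                    x_km=reef.x_km,
                    y_km=reef.y_km,
                    secondary_profile=secondary,
                    minor_fraction=minor,
                )
            )
    return out


def _haplotype_codes(seqs: Mapping[str, str], genes: Sequence[str]) -> np.ndarray:
    cat = "".join(seqs[g] for g in genes)
    arr = np.frombuffer(cat.encode(), dtype="S1")
    codes = np.zeros(len(arr), dtype=np.int64)
    for i, b in enumerate(BASES):
        codes[arr == b.encode()] = i
    return codes


def simulate_pileup_frame(
    colonies: Sequence[ColonyRecord],
    references: Sequence[GeneReference],
    profiles: Sequence[ProfileDefinition],
    config: SimulationConfig,
    sites: Sequence[tuple[str, int]] | None = None,
) -> pd.DataFrame:
    """Simulate pileup counts for many colonies as one tabular frame.

    Per-site depth is Poisson(``mean_depth``) (or ``fixed_depth``); reads
    are drawn from the colony's (possibly two-profile) haplotype mixture
    and each read is substituted, with probability ``error_rate``,
    uniformly to one of the three other bases. ``sites`` restricts output
    to selected (gene, position) coordinates, e.g. the diagnostic panel.
    """
    rng = np.random.default_rng(config.seed + 1)
    by_id = {p.profile_id: p for p in profiles}
    genes = sorted(r.gene_id for r in references)
    ref_seqs = {r.gene_id: r.sequence for r in references}
    gene_of = np.concatenate(
        [np.full(len(ref_seqs[g]), i) for i, g in enumerate(genes)]
    )
    pos_of = np.concatenate(
        [np.arange(1, len(ref_seqs[g]) + 1) for g in genes]
    )
    ref_codes = _haplotype_codes(ref_seqs, genes)
    if sites is not None:
        wanted = set(sites)
        mask = np.array(
            [(genes[gene_of[i]], int(pos_of[i])) in wanted
             for i in range(len(pos_of))]
        )
        sel = np.flatnonzero(mask)
    else:
        sel = np.arange(len(pos_of))
    l = len(sel)

    hap_cache: dict[str, np.ndarray] = {}

    def hap(pid: str) -> np.ndarray:
        if pid not in hap_cache:
            if pid not in by_id:
                raise KeyError(f"profile {pid!r} not defined")
            hap_cache[pid] = _haplotype_codes(
                haplotype_sequences(by_id[pid], references), genes
            )[sel]
        return hap_cache[pid]

    frames = []
    base_cols = np.array(["nA", "nC", "nG", "nT"])
    for colony in colonies:
        major = hap(colony.profile)
        if config.fixed_depth is not None:
            depth = np.full(l, config.fixed_depth, dtype=np.int64)
        else:
            depth = rng.poisson(config.mean_depth, size=l)
        if colony.secondary_profile is not None and colony.minor_fraction > 0:
            minor_hap = hap(colony.secondary_profile)
            n_minor = rng.binomial(depth, colony.minor_fraction)
        else:
            minor_hap = major
            n_minor = np.zeros(l, dtype=np.int64)
        counts = np.zeros((l, 4), dtype=np.int64)
        for source_hap, nreads in ((major, depth - n_minor), (minor_hap, n_minor)):
            if config.error_rate > 0:
                errs = rng.binomial(nreads, config.error_rate)
            else:
                errs = np.zeros(l, dtype=np.int64)
            np.add.at(counts, (np.arange(l), source_hap), nreads - errs)
            if errs.any():
                spread = rng.multinomial(errs, [1 / 3] * 3)
                others = np.array(
                    [[b for b in range(4) if b != h] for h in range(4)]
                )[source_hap]
                for k in range(3):
                    np.add.at(counts, (np.arange(l), others[:, k]), spread[:, k])
        df = pd.DataFrame(counts, columns=base_cols)
        df.insert(0, "colony", colony.colony_id)
        df.insert(1, "gene", np.array(genes)[gene_of[sel]])
        df.insert(2, "pos", pos_of[sel])
        df.insert(3, "ref", np.array(BASES)[ref_codes[sel]])
        df["nN"] = 0
        frames.append(df)
    return pd.concat(frames, ignore_index=True)[PILEUP_COLUMNS]


def simulate_pileups(
    colony: ColonyRecord,
    references: Sequence[GeneReference],
    profiles: Sequence[ProfileDefinition],
    config: SimulationConfig,
) -> list[PileupColumn]:
    """Simulate one colony's pileups as typed records (see
    :func:`simulate_pileup_frame` for the model and a bulk interface).

    The random stream is salted with the colony id so that per-colony calls
    under one config draw independent (but still seed-reproducible) noise.
    """
    import zlib
    from dataclasses import replace as _replace

    from chloropop.genotyping import frame_to_pileups

    salt = zlib.crc32(colony.colony_id.encode()) % (1 << 20)
    cfg = _replace(config, seed=config.seed + salt)
    return frame_to_pileups(
        simulate_pileup_frame([colony], references, profiles, cfg)
    )


def simulate_transplant(
    colonies: Sequence[ColonyRecord],
    sites: Sequence[str] | None = None,
    config: SimulationConfig = SimulationConfig(),
    all_colonies: Sequence[ColonyRecord] | None = None,
) -> list[TransplantRecord]:
    """Simulate the common-garden experiment for the given source colonies.

    Each colony yields 10 ramets, two per transplant site (nurseries 1 and
    2). Within a nursery, colonies fill four 25-position panels (A-D) of a
    5x5 grid; more than 100 source colonies exceed panel capacity. Survival
    is two-stage: immediate (transplant stress) then reef-specific one-year
    survival. A surviving, successfully genotyped ramet switches dominant
    profile with probability ``switch_rate``, adopting either the modal
    profile of the transplant reef's surveyed colonies (probability
    ``switch_local_weight``) or a random panel neighbour's native profile.

    ``all_colonies`` (default: ``colonies``) supplies the reef survey used
    for local dominant profiles.
    """
    if not colonies:
        raise ValueError("no colonies to transplant")
    if len(colonies) > 100:
        raise ValueError(
            f"{len(colonies)} colonies exceed panel capacity (4 panels x 25)"
        )
    survey = all_colonies if all_colonies is not None else colonies
    if sites is None:
        seen: list[str] = []
        for c in survey:
            if c.reef_id not in seen:
                seen.append(c.reef_id)
        sites = seen[:5]
    if len(sites) != len(config.site_survival):
        raise ValueError("need one survival rate per transplant site")

    by_reef: dict[str, dict[str, int]] = {}
    for c in survey:
        by_reef.setdefault(c.reef_id, {}).setdefault(c.profile, 0)
        by_reef[c.reef_id][c.profile] += 1
    modal = {
        reef: min(counts, key=lambda k: (-counts[k], k))
        for reef, counts in by_reef.items()
    }

    # panel placement: colonies in order fill panels A-D, 5x5 grid each
    placement = {}
    for i, c in enumerate(colonies):
        panel = "ABCD"[i // 25]
        within = i % 25
        placement[c.colony_id] = (panel, within // 5, within % 5)
    native_at = {
        (placement[c.colony_id][0],
         placement[c.colony_id][1],
         placement[c.colony_id][2]): c.profile
        for c in colonies
    }

    rng = np.random.default_rng(config.seed + 2)
    records: list[TransplantRecord] = []
    for site_idx, site in enumerate(sites):
        rate = config.site_survival[site_idx]
        for nursery in (1, 2):
            for c in colonies:
                panel, row, col = placement[c.colony_id]
                sample_id = f"{site}-{nursery}-{c.colony_id}"
                alive = (
                    rng.random() < config.immediate_survival
                    and rng.random() < rate
                )
                post = None
                if alive:
                    if rng.random() < config.post_call_rate:
                        post = c.profile
                        if rng.random() < config.switch_rate:
                            post = _switch_destination(
                                c, site, panel, row, col, modal, native_at,
                                config, rng,
                            )
                    else:
                        post = UNCALLED
                records.append(
                    TransplantRecord(
                        sample_id=sample_id,
                        native_reef=c.reef_id,
                        native_region=c.region_id,
                        native_profile=c.profile,
                        transplant_reef=site,
                        panel_id=f"{nursery}{panel}",
                        row=row,
                        col=col,
                        survived=alive,
                        post_profile=post,
                    )
                )
    return records


def _switch_destination(colony, site, panel, row, col, modal, native_at,
                        config, rng):
    """New dominant profile for a switching ramet."""
    use_local = rng.random() < config.switch_local_weight
    local = modal.get(site)
    neighbours = [
        native_at[(panel, row + dr, col + dc)]
        for dr in (-1, 0, 1)
        for dc in (-1, 0, 1)
        if (dr, dc) != (0, 0) and (panel, row + dr, col + dc) in native_at
    ]
    neighbours = [p for p in neighbours if p != colony.profile]
    if use_local and local is not None and local != colony.profile:
        return local
    if neighbours:
        return neighbours[int(rng.integers(0, len(neighbours)))]
    if local is not None and local != colony.profile:
        return local
    return colony.profile  # nothing different nearby: no observable switch
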