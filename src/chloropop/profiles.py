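"""Dominant chloroplast SNP-profile assignment and mixed-infection detection.

A *profile* is a class of concatenated chloroplast haplotypes defined by a
small panel of diagnostic SNPs (sites named ``gene.position``). Each colony
receives the unique profile consistent with its consensus bases at the
panel sites; colonies whose pileups show a credible second base at a
diagnostic site are flagged as harbouring a second profile. UPGMA trees of
the concatenated haplotypes provide an independent confirmation of the
panel-based calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from chloropop.genotyping import MISSING, _as_frame

AMBIGUOUS = "AMBIGUOUS"
UNCALLED = "UNCALLED"


@dataclass(frozen=True)
class PanelSite:
    gene_id: str
    position: int  # 1-based

    @property
    def name(self) -> str:
        return f"{self.gene_id}.{self.position}"

    @staticmethod
    def from_name(name: str) -> "PanelSite":
        gene, _, pos = name.rpartition(".")
        return PanelSite(gene, int(pos))


@dataclass(frozen=True)
class DiagnosticPanel:
    """Diagnostic SNP sites and the expected base of each profile at each.

    ``profile_bases`` maps profile id -> {site name -> base}. Every profile
    must be distinguishable from every other at >= 1 site.
    """

    sites: tuple[PanelSite, ...]
    profile_bases: Mapping[str, Mapping[str, str]]

    def __post_init__(self) -> None:
        names = [s.name for s in self.sites]
        if len(set(names)) != len(names):
            raise ValueError("panel site names must be unique")
        ids = self.profile_ids
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                if all(
                    self.profile_bases[a][s] == self.profile_bases[b][s]
                    for s in names
                ):
                    raise ValueError(
                        f"profiles {a!r} and {b!r} share identical panel bases"
                    )

    @property
    def profile_ids(self) -> list[str]:
        return list(self.profile_bases)

    @property
    def site_names(self) -> list[str]:
        return [s.name for s in self.sites]

    def base_to_profiles(self, site_name: str) -> dict[str, tuple[str, ...]]:
        """Inverse map at one site: observed base -> profiles carrying it."""
        out: dict[str, list[str]] = {}
        for pid, bases in self.profile_bases.items():
            out.setdefault(bases[site_name], []).append(pid)
        return {b: tuple(p) for b, p in out.items()}


@dataclass(frozen=True)
class ProfileCall:
    colony_id: str
    profile: str  # panel label, AMBIGUOUS or UNCALLED
    n_sites_used: int
    mismatch_count: int


@dataclass(frozen=True)
class MixedCall:
    colony_id: str
    variable_sites: tuple[tuple[str, dict, float], ...]  # (site, counts, minor frac)
    profile_pair: tuple[str, str] | None
    max_depth_ok: bool

    @property
    def is_mixed(self) -> bool:
        return len(self.variable_sites) > 0


def _panel_bases_from_sequences(
    sequences: Mapping[str, str], panel: DiagnosticPanel
) -> dict[str, str]:
    obs = {}
    for site in panel.sites:
        if site.gene_id not in sequences:
            raise KeyError(f"panel gene {site.gene_id!r} absent from sequences")
        seq = sequences[site.gene_id]
        if site.position > len(seq):
            raise ValueError(
                f"panel site {site.name} outside sequence (length {len(seq)})"
            )
        obs[site.name] = seq[site.position - 1]
    return obs


def assign_profile(
    sequences: Mapping[str, str],
    panel: DiagnosticPanel,
    colony_id: str = "",
    max_missing: int | None = None,
) -> ProfileCall:
    """Assign the dominant profile from consensus bases at the panel sites.

    ``sequences`` maps gene id -> consensus sequence. The call is the unique
    profile consistent with all non-N panel bases; if several are consistent
    the call is AMBIGUOUS, and if none is, the nearest profile by mismatch
    count wins (ties -> AMBIGUOUS). More than ``max_missing`` N sites
    (default: half the panel) yields UNCALLED.
    """
    if max_missing is None:
        max_missing = len(panel.sites) // 2
    obs = _panel_bases_from_sequences(sequences, panel)
    used = {k: v for k, v in obs.items() if v != MISSING}
    n_used = len(used)
    if len(panel.sites) - n_used > max_missing:
        return ProfileCall(colony_id, UNCALLED, n_used, 0)
    mismatches = {
        pid: sum(1 for s, b in used.items() if panel.profile_bases[pid][s] != b)
        for pid in panel.profile_ids
    }
    best = min(mismatches.values())
    winners = [pid for pid, m in mismatches.items() if m == best]
    profile = winners[0] if len(winners) == 1 else AMBIGUOUS
    return ProfileCall(colony_id, profile, n_used, best)


def detect_mixed(
    pileups,
    panel: DiagnosticPanel,
    min_depth: int = 5,
    min_minor_count: int = 2,
    min_minor_fraction: float = 0.10,
) -> list[MixedCall]:
    """Flag colonies whose pileups show two credible bases at panel sites.

    A panel site is *flagged* when its depth exceeds ``min_depth`` and the
    second-most frequent base has count >= ``min_minor_count`` and fraction
    >= ``min_minor_fraction``. A colony with >= 1 flagged site is mixed;
    ``profile_pair`` is the (dominant, secondary) profile pair jointly
    consistent with the major/minor bases when it is unique, else None.
    ``max_depth_ok`` records whether any panel site had depth above the
    threshold (insufficient depth is not an error).

    Returns one MixedCall per colony present in the pileups.
    """
    frame = _as_frame(pileups)
    site_index = {(s.gene_id, s.position): s.name for s in panel.sites}
    keys = list(zip(frame["gene"], frame["pos"]))
    mask = np.array([k in site_index for k in keys])
    sub = frame.loc[mask]

    out = []
    for colony, grp in sub.groupby("colony", sort=True):
        variable = []
        major_bases: dict[str, str] = {}
        any_depth_ok = False
        for row in grp.itertuples(index=False):
            name = site_index[(row.gene, row.pos)]
            counts = np.array([row.nA, row.nC, row.nG, row.nT], dtype=np.int64)
            depth = int(counts.sum())
            if depth <= min_depth:
                continue
            any_depth_ok = True
            order = np.argsort(counts, kind="stable")[::-1]
            major, minor = order[0], order[1]
            major_bases[name] = "ACGT"[major]
            minor_count = int(counts[minor])
            frac = minor_count / depth
            if minor_count >= min_minor_count and frac >= min_minor_fraction:
                variable.append(
                    (name, {b: int(c) for b, c in zip("ACGT", counts)},
                     float(frac), "ACGT"[minor])
                )
        pair = _infer_profile_pair(panel, major_bases, variable) if variable else None
        out.append(
            MixedCall(
                colony_id=str(colony),
                variable_sites=tuple((n, c, f) for n, c, f, _ in variable),
                profile_pair=pair,
                max_depth_ok=any_depth_ok,
            )
        )
    return out


def _infer_profile_pair(panel, major_bases, variable):
    """(dominant, secondary) profiles jointly consistent with the read data.

    The dominant profile must match the major base at every panel site with
    sufficient depth; the secondary must match the minor base at every
    flagged site and differ from the dominant. Returns the pair only when
    both are unique.
    """
    dominants = [
        pid
        for pid in panel.profile_ids
        if all(panel.profile_bases[pid][s] == b for s, b in major_bases.items())
    ]
    minor_by_site = {name: minor for name, _, _, minor in variable}
    secondaries = [
        pid
        for pid in panel.profile_ids
        if all(panel.profile_bases[pid][s] == b for s, b in minor_by_site.items())
    ]
    if len(dominants) == 1 and len(secondaries) == 1 and dominants[0] != secondaries[0]:
        return (dominants[0], secondaries[0])
    return None


@dataclass(frozen=True)
class UniqueHaplotype:
    sequence: str
    multiplicity: int
    members: tuple[str, ...]


def collapse_unique(
    labeled_haplotypes: Mapping[str, str] | Iterable[tuple[str, str]],
) -> list[UniqueHaplotype]:
    """Deduplicate concatenated haplotypes by exact string identity.

    N is treated as a distinct character so that missing data never merges
    haplotypes. Output is sorted by descending multiplicity then sequence,
    and multiplicities sum to the input count.
    """
    items = (
        list(labeled_haplotypes.items())
        if isinstance(labeled_haplotypes, Mapping)
        else list(labeled_haplotypes)
    )
    if not items:
        return []
    lengths = {len(seq) for _, seq in items}
    if len(lengths) > 1:
        raise ValueError(f"haplotypes differ in length: {sorted(lengths)}")
    groups: dict[str, list[str]] = {}
    for label, seq in items:
        groups.setdefault(seq, []).append(label)
    return sorted(
        (
            UniqueHaplotype(seq, len(members), tuple(members))
            for seq, members in groups.items()
        ),
        key=lambda u: (-u.multiplicity, u.sequence),
    )


def p_distance_matrix(haplotypes: Sequence[str]) -> np.ndarray:
    """Pairwise p-distance: mismatches / sites non-N in both sequences."""
    n = len(haplotypes)
    if n < 2:
        raise ValueError("need >= 2 haplotypes")
    lengths = {len(s) for s in haplotypes}
    if len(lengths) > 1:
        raise ValueError("haplotypes must have equal length")
    mat = np.frombuffer("".join(haplotypes).encode(), dtype="S1").reshape(n, -1)
    ok = mat != b"N"
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"haplotypes {i} and {j} share no comparable sites"
                )
            d[i, j] = d[j, i] = int(((mat[i] != mat[j]) & both).sum()) / m
    return d


@dataclass
class TreeNode:
    """Node of an ultrametric average-linkage tree."""

    label: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    height: float = 0.0  # distance from this node down to any leaf
    branch_length: float = 0.0  # to the parent

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [lf for c in self.children for lf in c.leaves()]


def _quote_label(label: str) -> str:
    if label == "" or any(ch in label for ch in "(),:;'\" \t[]"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _newick(node: TreeNode, with_length: bool) -> str:
    if node.is_leaf:
        s = _quote_label(node.label or "")
    else:
        s = "(" + ",".join(_newick(c, with_length) for c in node.children) + ")"
    if with_length:
        s += f":{node.branch_length:.10g}"
    return s


@dataclass
class HaplotypeTree:
    """UPGMA tree over unique haplotypes; branch lengths in subs/site."""

    root: TreeNode
    multiplicities: Mapping[str, int] | None = None

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.label for lf in self.root.leaves()]

    def to_newick(self, with_lengths: bool = True) -> str:
        inner = _newick(self.root, with_lengths)
        if with_lengths:
            # the root itself carries no branch
            inner = inner.rsplit(":", 1)[0] if not self.root.is_leaf else inner
        return inner + ";"

    def leaf_depths(self) -> dict[str, float]:
        depths = {}

        def walk(node: TreeNode, acc: float) -> None:
            if node.is_leaf:
                depths[node.label] = acc
            for c in node.children:
                walk(c, acc + c.branch_length)

        walk(self.root, 0.0)
        return depths

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        d = list(self.leaf_depths().values())
        return max(d) - min(d) <= tol


def upgma_tree(
    distances: np.ndarray,
    labels: Sequence[str],
    multiplicities: Mapping[str, int] | None = None,
) -> HaplotypeTree:
    """Average-linkage (UPGMA) agglomeration of a distance matrix.

    Merge height is half the average-linkage distance, giving an ultrametric
    tree. Ties are broken by the lexicographically smallest pair of cluster
    representatives (a cluster is represented by its smallest leaf label),
    so output is deterministic.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if d.shape[0] != len(labels):
        raise ValueError("labels must match matrix size")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    if not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must have a zero diagonal")

    nodes = {i: TreeNode(label=labels[i]) for i in range(len(labels))}
    sizes = {i: 1 for i in range(len(labels))}
    reps = {i: labels[i] for i in range(len(labels))}
    dist = {
        (i, j): d[i, j]
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    }
    if len(labels) == 1:
        return HaplotypeTree(root=nodes[0], multiplicities=multiplicities)

    next_id = len(labels)
    while len(nodes) > 1:
        (i, j) = min(
            dist,
            key=lambda ij: (dist[ij], min(reps[ij[0]], reps[ij[1]]),
                            max(reps[ij[0]], reps[ij[1]])),
        )
        dij = dist[(i, j)]
        height = dij / 2.0
        for k in (i, j):
            nodes[k].branch_length = height - nodes[k].height
        first, second = (i, j) if reps[i] <= reps[j] else (j, i)
        parent = TreeNode(children=[nodes[first], nodes[second]], height=height)
        # average linkage update over the remaining clusters
        new_dist = {}
        for k in nodes:
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            new_dist[k] = (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
        dist = {
            (a, b): v
            for (a, b), v in dist.items()
            if i not in (a, b) and j not in (a, b)
        }
        del nodes[i], nodes[j]
        sizes[next_id] = sizes.pop(i) + sizes.pop(j)
        reps[next_id] = min(reps.pop(i), reps.pop(j))
        for k, v in new_dist.items():
            dist[(min(k, next_id), max(k, next_id))] = v
        nodes[next_id] = parent
        next_id += 1

    root = nodes.popitem()[1]
    return HaplotypeTree(root=root, multiplicities=multiplicities)
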