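"""Common-garden transplant analysis: symbiont switching and survival.

Each transplanted ramet is identified as ``transplantReef-nursery-colony``
(e.g. ``7-1-257``). A *switch* is a ramet whose post-transplant dominant
profile differs from its native call; switch destinations are classified
by where the new profile could have come from: the transplant reef's
dominant profile, a neighbouring ramet on the transplant panel, the native
reef's profile pool, or nowhere observed (novel).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

UNCALLED = "UNCALLED"

LOCAL_DOMINANT = "LOCAL_DOMINANT"
PANEL_NEIGHBOR = "PANEL_NEIGHBOR"
NATIVE_PRESENT = "NATIVE_PRESENT"
NOVEL = "NOVEL"
CATEGORY_PRECEDENCE = (LOCAL_DOMINANT, PANEL_NEIGHBOR, NATIVE_PRESENT, NOVEL)

_SAMPLE_ID_RE = re.compile(r"^(\d+)-(\d+)-(\d+)$")


@dataclass(frozen=True)
class TransplantRecord:
    """One ramet of the common-garden experiment."""

    sample_id: str
    native_reef: str
    native_profile: str
    transplant_reef: str
    panel_id: str = ""
    row: int = 0
    col: int = 0
    survived: bool = False
    post_profile: str | None = None  # profile label or UNCALLED; None if dead
    native_region: str | None = None

    def __post_init__(self) -> None:
        if self.post_profile is not None and not self.survived:
            raise ValueError(
                f"{self.sample_id}: post_profile present for a dead ramet"
            )


@dataclass(frozen=True)
class SwitchRecord:
    sample_id: str
    from_profile: str
    to_profile: str
    category: str | None = None
    evidence: tuple[str, ...] = ()


@dataclass
class SwitchSummary:
    switches: list[SwitchRecord]
    n_assayed: int  # ramets with both native and post calls
    n_switched: int

    @property
    def fraction(self) -> float:
        return self.n_switched / self.n_assayed if self.n_assayed else float("nan")


def parse_sample_id(sample_id: str) -> tuple[int, int, int]:
    """Split ``transplantReef-nursery-colony`` into its three integers."""
    m = _SAMPLE_ID_RE.match(sample_id)
    if not m:
        raise ValueError(
            f"malformed sample id {sample_id!r}: expected integer-dash-"
            "integer-dash-integer"
        )
    return tuple(int(g) for g in m.groups())


def detect_switches(records: Sequence[TransplantRecord]) -> SwitchSummary:
    """Find ramets whose post-transplant profile differs from the native one.

    Ramets without a usable post-transplant call (dead, or post profile
    UNCALLED/absent) are excluded from both numerator and denominator.
    """
    switches = []
    n_assayed = 0
    for r in records:
        if not r.survived or r.post_profile in (None, UNCALLED):
            continue
        if r.native_profile in (None, UNCALLED):
            continue
        n_assayed += 1
        if r.post_profile != r.native_profile:
            switches.append(
                SwitchRecord(
                    sample_id=r.sample_id,
                    from_profile=r.native_profile,
                    to_profile=r.post_profile,
                )
            )
    return SwitchSummary(switches=switches, n_assayed=n_assayed,
                         n_switched=len(switches))


def _modal_profile(counts: Mapping[str, int | float]) -> str:
    # deterministic: ties break alphabetically
    return min(counts, key=lambda k: (-counts[k], k))


def _neighbors(position: tuple[int, int], radius: int, connectivity: int):
    r0, c0 = position
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            if dr == 0 and dc == 0:
                continue
            if connectivity == 4 and abs(dr) + abs(dc) > radius:
                continue
            yield (r0 + dr, c0 + dc)


def classify_switch_destination(
    switch: SwitchRecord,
    transplant_reef_counts: Mapping[str, int | float],
    native_reef_profiles: Iterable[str],
    panel_layout: Mapping[tuple[int, int], str] | None = None,
    position: tuple[int, int] | None = None,
    connectivity: int = 8,
    radius: int = 1,
) -> SwitchRecord:
    """Classify where a switched ramet's new profile could have come from.

    Evidence flags are collected for every satisfied source and the
    category is the highest-precedence one: LOCAL_DOMINANT (the new profile
    is the modal dominant profile among surveyed colonies of the transplant
    reef) > PANEL_NEIGHBOR (a grid neighbour's native profile matches;
    8-neighbourhood by default) > NATIVE_PRESENT (the profile occurs on the
    native reef) > NOVEL.
    """
    if not transplant_reef_counts:
        raise KeyError("transplant reef has no surveyed profile counts")
    evidence = []
    if switch.to_profile == _modal_profile(transplant_reef_counts):
        evidence.append(LOCAL_DOMINANT)
    if panel_layout is not None and position is not None:
        for pos in _neighbors(position, radius, connectivity):
            if panel_layout.get(pos) == switch.to_profile:
                evidence.append(PANEL_NEIGHBOR)
                break
    if switch.to_profile in set(native_reef_profiles):
        evidence.append(NATIVE_PRESENT)
    category = next((c for c in CATEGORY_PRECEDENCE if c in evidence), NOVEL)
    return replace(switch, category=category, evidence=tuple(evidence))


def classify_switches(
    summary: SwitchSummary,
    records: Sequence[TransplantRecord],
    reef_profile_counts: Mapping[str, Mapping[str, int | float]],
    connectivity: int = 8,
) -> list[SwitchRecord]:
    """Classify every switch using per-reef profile counts and panel maps.

    ``reef_profile_counts`` maps reef id -> {profile -> count} of surveyed
    native colonies. The panel layout of each (transplant reef, panel) is
    rebuilt from the records' grid positions and native profiles.
    """
    by_id = {r.sample_id: r for r in records}
    layouts: dict[tuple[str, str], dict[tuple[int, int], str]] = {}
    for r in records:
        layouts.setdefault((r.transplant_reef, r.panel_id), {})[(r.row, r.col)] = (
            r.native_profile
        )
    out = []
    for sw in summary.switches:
        rec = by_id[sw.sample_id]
        if rec.transplant_reef not in reef_profile_counts:
            raise KeyError(f"no profile counts for reef {rec.transplant_reef!r}")
        native_counts = reef_profile_counts.get(rec.native_reef, {})
        layout = dict(layouts[(rec.transplant_reef, rec.panel_id)])
        layout.pop((rec.row, rec.col), None)  # not our own position
        out.append(
            classify_switch_destination(
                sw,
                transplant_reef_counts=reef_profile_counts[rec.transplant_reef],
                native_reef_profiles=native_counts.keys(),
                panel_layout=layout,
                position=(rec.row, rec.col),
                connectivity=connectivity,
            )
        )
    return out


def survival_summary(
    records: Sequence[TransplantRecord],
) -> dict[str, pd.Series | pd.DataFrame]:
    """Percent survival by transplant reef, native region and native profile.

    Percentages are survivors / deployed * 100 per stratum; empty strata
    are NaN. ``overall`` holds deployed and survivor counts.
    """
    df = pd.DataFrame(
        {
            "transplant_reef": [r.transplant_reef for r in records],
            "native_region": [r.native_region for r in records],
            "native_profile": [r.native_profile for r in records],
            "survived": [bool(r.survived) for r in records],
        }
    )

    def pct(by: str) -> pd.Series:
        g = df.groupby(by, dropna=False)["survived"]
        return (100.0 * g.mean()).rename("percent_survival")

    return {
        "by_transplant_reef": pct("transplant_reef"),
        "by_native_region": pct("native_region"),
        "by_native_profile": pct("native_profile"),
        "overall": pd.Series(
            {
                "deployed": len(df),
                "survivors": int(df["survived"].sum()),
                "percent": 100.0 * df["survived"].mean() if len(df) else np.nan,
            }
        ),
    }


def per_colony_rollup(summary: SwitchSummary) -> pd.DataFrame:
    """Switch counts aggregated per native colony (parsed from sample ids)."""
    rows = []
    for sw in summary.switches:
        reef, nursery, colony = parse_sample_id(sw.sample_id)
        rows.append((colony, sw.sample_id, sw.from_profile, sw.to_profile))
    df = pd.DataFrame(rows, columns=["colony", "sample_id", "from", "to"])
    if df.empty:
        return pd.DataFrame(columns=["colony", "n_ramets_switched"])
    return (
        df.groupby("colony")
        .size()
        .rename("n_ramets_switched")
        .reset_index()
        .sort_values("colony", ignore_index=True)
    )
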