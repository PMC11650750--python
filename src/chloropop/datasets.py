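"""Small bundled example datasets.

``switch_table()`` holds the published record of the 12 ramets that changed
dominant chloroplast SNP profile in a one-year, five-site common-garden
transplant experiment in Palau (79 source colonies, 10 ramets each, 91
ramets with both a native and a post-transplant profile call). Sample ids
are ``transplantReef-nursery-colony``. ``profiles_at_*`` columns list the
dominant profiles surveyed at the transplant and native reefs.

``host_lineage_table()`` is the published 2x2 contingency table of symbiont
profile (U3 vs L) against host cryptic lineage (CS1 vs CS5) for southern-
region colonies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from chloropop.transplant import TransplantRecord

_SWITCH_ROWS = [
    # sample, native reef, native profile, post profile,
    # profiles at transplant reef, profiles at native reef
    ("7-1-257", "39", "U1", "L", ("U1",), ("U1", "L")),
    ("7-1-003", "7", "L", "U1", ("U1",), ("U1",)),
    ("7-1-156", "27", "L", "U1", ("U1",), ("U1", "L")),
    ("7-1-203", "30", "U1", "U2", ("U1",), ("U1", "U2", "L")),
    ("7-2-066", "15", "U3", "U1", ("U1",), ("U1", "U3")),
    ("7-2-064", "15", "U1", "U3", ("U1",), ("U1", "U3")),
    ("9-1-036", "17", "U1", "L", ("U1", "L"), ("U1", "L")),
    ("9-1-032", "17", "L", "U1", ("U1", "L"), ("U1", "L")),
    ("9-1-386", "61", "U3", "U1", ("U1", "L"), ("U1", "L")),
    ("21-1-036", "17", "U1", "L", ("U1", "L"), ("U1", "L")),
    ("21-1-386", "61", "L", "U1", ("U1", "L"), ("U1", "L")),
    ("27-1-065", "15", "U1", "U3", ("U1", "L"), ("U1", "U3")),
]

N_ASSAYED_RAMETS = 91  # ramets with both native and post-transplant calls


def switch_table() -> pd.DataFrame:
    """The 12 published profile-change ramets as a DataFrame."""
    return pd.DataFrame(
        _SWITCH_ROWS,
        columns=[
            "sample_id", "native_reef", "native_profile", "post_profile",
            "profiles_at_transplant_reef", "profiles_at_native_reef",
        ],
    )


def switch_records(n_unchanged: int | None = None) -> list[TransplantRecord]:
    """The published switches as TransplantRecords, padded with unchanged
    surviving ramets so the assayed denominator is ``N_ASSAYED_RAMETS``.

    Filler ramets keep their native profile; their ids continue the
    published naming scheme on transplant reef 7.
    """
    if n_unchanged is None:
        n_unchanged = N_ASSAYED_RAMETS - len(_SWITCH_ROWS)
    records = [
        TransplantRecord(
            sample_id=s, native_reef=nr, native_profile=np_, survived=True,
            transplant_reef=s.split("-")[0], post_profile=pp,
        )
        for s, nr, np_, pp, _, _ in _SWITCH_ROWS
    ]
    for i in range(n_unchanged):
        records.append(
            TransplantRecord(
                sample_id=f"7-2-{500 + i}", native_reef="7",
                native_profile="U1", transplant_reef="7", survived=True,
                post_profile="U1",
            )
        )
    return records


def host_lineage_table() -> np.ndarray:
    """U3:L counts among CS1 (9:10) vs CS5 (7:19) southern colonies."""
    return np.array([[9, 7], [10, 19]])
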