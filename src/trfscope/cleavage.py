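"""Normalized-cleavage profiles and m7G site calling.

Aniline scission at abasic sites generated from N7-methylguanosine leaves the
downstream fragment's 5' end immediately 3' of the modified base, so a
per-position pileup of read 5' extremities carries the modification signal.
The normalized cleavage of a position is its 5'-end count divided by the total
reads mapped to that RNA species; knockout (methyltransferase-null) profiles
serve as controls when calling sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .reference import TRNAReference, g46_subset

__all__ = [
    "CleavageProfile",
    "ncleavage",
    "call_m7g_sites",
    "cleavage_matrix",
    "read_profiles",
    "write_profiles",
]


@dataclass
class CleavageProfile:
    """Per-position 5'-end counts for one species/condition/replicate."""

    species_id: str
    condition: str
    replicate: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError(
                f"profile {self.species_id}/{self.replicate}: negative counts"
            )

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def ncleavage(profile: CleavageProfile) -> np.ndarray:
    """Per-position fractions: count at each position over the species total.

    Fractions sum to 1.  A zero-total profile yields an all-zero vector with a
    warning (such species are excluded from site calling).
    """
    total = profile.total
    if total == 0:
        warnings.warn(
            f"profile {profile.species_id}/{profile.replicate}: zero total, "
            "excluded from site calling"
        )
        return np.zeros_like(profile.counts, dtype=float)
    return profile.counts / total


def _mean_fractions(
    profiles: Sequence[CleavageProfile],
) -> dict[str, tuple[np.ndarray, float]]:
    """Per species: mean normalized cleavage across replicates + mean total."""
    out: dict[str, tuple[list[np.ndarray], list[int]]] = {}
    for p in profiles:
        if p.total == 0:
            ncleavage(p)  # emits the warning
            continue
        out.setdefault(p.species_id, ([], []))
        out[p.species_id][0].append(ncleavage(p))
        out[p.species_id][1].append(p.total)
    return {
        sid: (np.mean(fracs, axis=0), float(np.mean(totals)))
        for sid, (fracs, totals) in out.items()
    }


def call_m7g_sites(
    wt: Sequence[CleavageProfile],
    ko: Sequence[CleavageProfile],
    ref: TRNAReference,
    min_frac: float = 0.05,
    min_ratio: float = 5.0,
    offset: int = 1,
) -> pd.DataFrame:
    """Call methylated guanosines from WT-vs-KO normalized cleavage.

    A pileup position ``p`` is a candidate when the inferred modified base at
    ``p - offset`` is a guanosine.  The candidate is called when the mean WT
    fraction at ``p`` reaches ``min_frac`` and the smoothed WT/KO ratio
    ``(wt + d) / (ko + d)`` reaches ``min_ratio``, with ``d`` = 1 / (mean
    replicate total for the species).  The reported site is ``p - offset``
    (the G itself); within a species, candidates are ordered by the WT - KO
    difference (largest first, the tie-break).

    Returns a table with columns ``species_id, position, position_1based,
    wt_frac, ko_frac, ratio, called`` containing every candidate that passes
    the ``min_frac`` gate (called or not).
    """
    wt_means = _mean_fractions(wt)
    ko_means = _mean_fractions(ko)
    missing = (set(wt_means) - set(ko_means)) | (set(ko_means) - set(wt_means))
    if missing:
        raise ValueError(
            f"species present in only one condition: {sorted(missing)}"
        )
    rows = []
    for sid in wt_means:
        if sid not in ref:
            raise ValueError(f"profile species {sid!r} not in reference")
        seq = ref[sid].sequence
        wt_frac, wt_total = wt_means[sid]
        ko_frac, ko_total = ko_means[sid]
        if len(wt_frac) != len(seq) or len(ko_frac) != len(seq):
            raise ValueError(f"profile length mismatch for species {sid!r}")
        delta = 1.0 / ((wt_total + ko_total) / 2.0)
        for p in range(len(seq)):
            site = p - offset
            if site < 0 or seq[site] != "G":
                continue
            if wt_frac[p] < min_frac:
                continue
            ratio = (wt_frac[p] + delta) / (ko_frac[p] + delta)
            rows.append(
                {
                    "species_id": sid,
                    "position": site,
                    "position_1based": site + 1,
                    "wt_frac": wt_frac[p],
                    "ko_frac": ko_frac[p],
                    "ratio": ratio,
                    "diff": wt_frac[p] - ko_frac[p],
                    "called": bool(ratio >= min_ratio),
                }
            )
    cols = [
        "species_id",
        "position",
        "position_1based",
        "wt_frac",
        "ko_frac",
        "ratio",
        "diff",
        "called",
    ]
    out = pd.DataFrame(rows, columns=cols)
    if len(out):
        out = out.sort_values(
            ["species_id", "diff"], ascending=[True, False]
        ).reset_index(drop=True)
    return out


def cleavage_matrix(
    ref: TRNAReference, profiles: Sequence[CleavageProfile], offset: int = 1
) -> pd.DataFrame:
    """Species x replicate matrix of normalized cleavage at each species' site.

    Restricted to the annotated (m7G-candidate) species; each cell is the
    normalized cleavage at ``m7g_pos + offset`` for one condition replicate.
    Species absent from the profiles get NaN rows (missing, not zero).
    """
    annotated = g46_subset(ref)
    columns: list[str] = []
    for p in profiles:
        col = f"{p.condition}:{p.replicate}"
        if col not in columns:
            columns.append(col)
    mat = pd.DataFrame(np.nan, index=annotated.ids, columns=columns)
    for p in profiles:
        if p.species_id not in annotated:
            continue
        sp = annotated[p.species_id]
        frac = ncleavage(p)
        pos = sp.m7g_pos + offset
        if pos < len(frac):
            mat.loc[p.species_id, f"{p.condition}:{p.replicate}"] = frac[pos]
    return mat


def write_profiles(profiles: Iterable[CleavageProfile], path: str | Path) -> None:
    """Long-format TSV: species, condition, replicate, position (0-based), count."""
    rows = []
    for p in profiles:
        for pos, c in enumerate(p.counts):
            rows.append((p.species_id, p.condition, p.replicate, pos, int(c)))
    pd.DataFrame(
        rows, columns=["species_id", "condition", "replicate", "position", "count"]
    ).to_csv(path, sep="\t", index=False)


def read_profiles(path: str | Path) -> list[CleavageProfile]:
    df = pd.read_csv(path, sep="\t")
    profiles = []
    for (sid, cond, rep), grp in df.groupby(
        ["species_id", "condition", "replicate"], sort=False
    ):
        length = int(grp["position"].max()) + 1
        counts = np.zeros(length, dtype=np.int64)
        counts[grp["position"].to_numpy()] = grp["count"].to_numpy()
        profiles.append(
            CleavageProfile(
                species_id=sid, condition=cond, replicate=str(rep), counts=counts
            )
        )
    return profiles
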