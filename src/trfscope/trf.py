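"""tRNA-derived fragment (tRF) taxonomy and abundance/length filters.

Retained fragments are partitioned into mutually exclusive classes:

* ``FIVE_HALF``   — 5'-anchored, longer than 35 nt (5' tRNA halves)
* ``FIVE_TOG``    — 5'-anchored, <= 35 nt, with a 5' terminal oligoguanine run
* ``FIVE_PRIME_TRF`` — 5'-anchored, <= 35 nt, without the terminal G run
* ``THREE_PRIME_TRF`` — ends within 10 nt of the tRNA 3' end
* ``INT_TRF``     — spans the interior of the mature tRNA
* ``AMBIGUOUS``   — multi-mapped fragments whose loci disagree on the class

"5'-anchored" means the fragment starts within the first 10 nt of the mature
tRNA (0-based start < 10); a mature-tRNA reference admits no upstream starts,
so no lower bound applies.  The rules are applied in priority order
5' > 3' > internal, which is only consequential for pathologically short
species.  The global length filter retains fragments of 18-50 nt.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Literal

import pandas as pd

from .fragmentio import FragmentCountTable, Locus
from .reference import TRNAReference

__all__ = [
    "TRFClass",
    "ClassifyParams",
    "ClassifiedTable",
    "tog_run",
    "classify_fragment",
    "classify_table",
    "filter_low_counts",
    "class_composition",
]


class TRFClass(str, Enum):
    THREE_PRIME_TRF = "3'tRF"
    INT_TRF = "int-tRF"
    FIVE_PRIME_TRF = "5'tRF"
    FIVE_HALF = "5'half"
    FIVE_TOG = "5'TOG"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class ClassifyParams:
    """Tunable boundaries of the taxonomy.

    ``min_tog_g`` defaults to 4: the Ala-derived terminal-oligoguanine
    fragments carry 4 G, the Cys-derived ones 5.  ``half_min_len`` is the
    strict 5'-half threshold (> 35 nt); ``end_window``/``start_window`` are the
    anchoring windows at the tRNA extremities.  ``len_min``/``len_max`` bound
    the retained fragment lengths.
    """

    min_tog_g: int = 4
    half_min_len: int = 35  # strict: length > 35 is a 5'-half
    start_window: int = 10
    end_window: int = 10
    len_min: int = 18
    len_max: int = 50


def tog_run(seq: str) -> int:
    """Length of the maximal run of consecutive G at the 5' terminus."""
    if not seq:
        raise ValueError("empty sequence")
    return len(seq) - len(seq.lstrip("G"))


def classify_fragment(
    locus: Locus, seq: str, trna_len: int, params: ClassifyParams = ClassifyParams()
) -> TRFClass:
    """Classify one fragment at one locus.

    Priority: 5'-anchored (start < ``start_window``), then 3'-anchored
    (distance from tRNA end < ``end_window``), then internal.  Within the
    5'-anchored branch: length > ``half_min_len`` is a 5'-half, else a terminal
    G run of at least ``min_tog_g`` makes a 5'TOG, else a plain 5'tRF.
    """
    _, start, end = locus
    if not (0 <= start < end <= trna_len):
        raise ValueError(f"locus {locus} outside species of length {trna_len}")
    length = end - start
    if len(seq) != length:
        raise ValueError(f"sequence length {len(seq)} != locus span {length}")
    if start < params.start_window:
        if length > params.half_min_len:
            return TRFClass.FIVE_HALF
        if tog_run(seq) >= params.min_tog_g:
            return TRFClass.FIVE_TOG
        return TRFClass.FIVE_PRIME_TRF
    if trna_len - end < params.end_window:
        return TRFClass.THREE_PRIME_TRF
    return TRFClass.INT_TRF


@dataclass
class ClassifiedTable:
    """A :class:`FragmentCountTable` with per-row class, tog_run and length."""

    table: FragmentCountTable
    annotations: pd.DataFrame  # columns: trf_class, tog_run, length

    @property
    def counts(self) -> pd.DataFrame:
        return self.table.counts

    @property
    def loci(self) -> dict[str, tuple[Locus, ...]]:
        return self.table.loci

    def to_frame(self) -> pd.DataFrame:
        out = self.table.to_frame()
        out.insert(1, "trf_class", self.annotations["trf_class"])
        out.insert(2, "tog_run", self.annotations["tog_run"])
        out.insert(3, "length", self.annotations["length"])
        return out


def classify_table(
    table: FragmentCountTable,
    ref: TRNAReference,
    params: ClassifyParams = ClassifyParams(),
    ambiguous_policy: Literal["ambiguous", "majority"] = "ambiguous",
) -> ClassifiedTable:
    """Classify every fragment row via its loci and apply the length filter.

    Rows with length outside [``len_min``, ``len_max``] are removed.  When a
    row's loci disagree on the class, the default policy labels it
    ``AMBIGUOUS``; the ``majority`` policy takes the most common class (ties
    fall back to ``AMBIGUOUS``).
    """
    keep: list[str] = []
    rows = []
    for seq in table.counts.index:
        length = len(seq)
        if not params.len_min <= length <= params.len_max:
            continue
        classes = []
        for locus in table.loci[seq]:
            sid = locus[0]
            if sid not in ref:
                raise ValueError(f"locus species {sid!r} not in reference")
            classes.append(classify_fragment(locus, seq, ref[sid].length, params))
        distinct = set(classes)
        if len(distinct) == 1:
            label = classes[0]
        elif ambiguous_policy == "majority":
            tally = pd.Series(classes).value_counts()
            label = (
                TRFClass(tally.index[0])
                if len(tally) == 1 or tally.iloc[0] > tally.iloc[1]
                else TRFClass.AMBIGUOUS
            )
        else:
            label = TRFClass.AMBIGUOUS
        keep.append(seq)
        rows.append(
            {"trf_class": label.value, "tog_run": tog_run(seq), "length": length}
        )
    counts = table.counts.loc[keep]
    return ClassifiedTable(
        table=FragmentCountTable(
            counts=counts, loci={s: table.loci[s] for s in keep}
        ),
        annotations=pd.DataFrame(rows, index=keep),
    )


def filter_low_counts(
    classified: ClassifiedTable, min_total: int = 10, pseudocount: int = 1
) -> ClassifiedTable:
    """Drop rows with total raw count < ``min_total``; add ``pseudocount``
    to every retained cell."""
    totals = classified.counts.sum(axis=1)
    keep = totals[totals >= min_total].index
    counts = classified.counts.loc[keep] + pseudocount
    return ClassifiedTable(
        table=FragmentCountTable(
            counts=counts, loci={s: classified.loci[s] for s in keep}
        ),
        annotations=classified.annotations.loc[keep],
    )


def class_composition(
    classified: ClassifiedTable, subset: pd.Index | list[str] | None = None
) -> pd.Series:
    """Percentage of rows per class (sums to 100), optionally on a row subset.

    Passing the index of, e.g., the differentially abundant rows recomputes
    the composition on that subset.
    """
    ann = classified.annotations
    if subset is not None:
        ann = ann.loc[[s for s in subset]]
    if len(ann) == 0:
        raise ValueError("empty table has no class composition")
    return 100.0 * ann["trf_class"].value_counts() / len(ann)
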