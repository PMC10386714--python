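"""Compact mature-tRNA reference with structural annotations.

A :class:`TRNAReference` holds the mature tRNA species that every downstream
stage (fragment alignment, tRF classification, cleavage-profile site calling)
works against.  Each species carries, besides its RNA sequence, the position of
the candidate N7-methylguanosine in the variable loop (``m7g_pos``) and the
variable-loop interval itself.  Coordinates are 0-based, half-open internally;
user-facing summaries report 1-based closed positions.

The on-disk representation is a FASTA file of sequences plus a TSV annotation
table with columns ``id``, ``amino_acid``, ``anticodon``, ``m7g_pos``,
``var_loop_start``, ``var_loop_end`` (all coordinates in the table are 0-based,
``var_loop_end`` exclusive; ``m7g_pos`` may be empty for species without an
annotated variable-loop guanosine).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGU")

__all__ = [
    "RNA_ALPHABET",
    "TRNASpecies",
    "TRNAReference",
    "load_reference",
    "write_reference",
    "g46_subset",
    "reference_summary",
]


@dataclass(frozen=True)
class TRNASpecies:
    """One mature tRNA species.

    Parameters
    ----------
    id : str
        Unique identifier, e.g. ``"Cys-GCA-sim1"``.
    amino_acid : str
        Three-letter amino-acid code of the isoacceptor family.
    anticodon : str
        Anticodon trinucleotide over {A, C, G, U}.
    sequence : str
        Mature RNA sequence (DNA input must be transcribed before construction).
    m7g_pos : int or None
        0-based index of the candidate m7G guanosine inside the variable loop,
        or ``None`` when the species carries no annotated site.
    var_loop : (int, int)
        Half-open 0-based interval of the variable loop within the sequence.
    """

    id: str
    amino_acid: str
    anticodon: str
    sequence: str
    m7g_pos: Optional[int] = None
    var_loop: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ValueError(
                f"species {self.id!r}: non-RNA characters {sorted(bad)} in sequence"
            )
        if len(self.anticodon) != 3 or set(self.anticodon) - RNA_ALPHABET:
            raise ValueError(f"species {self.id!r}: invalid anticodon {self.anticodon!r}")
        start, end = self.var_loop
        if not (0 <= start <= end <= len(self.sequence)):
            raise ValueError(
                f"species {self.id!r}: variable loop {self.var_loop} outside [0, {len(self.sequence)})"
            )
        if self.m7g_pos is not None:
            if not (start <= self.m7g_pos < end):
                raise ValueError(
                    f"species {self.id!r}: m7g_pos {self.m7g_pos} outside variable loop {self.var_loop}"
                )
            if self.sequence[self.m7g_pos] != "G":
                raise ValueError(
                    f"species {self.id!r}: m7g_pos {self.m7g_pos} is "
                    f"{self.sequence[self.m7g_pos]!r}, not 'G'"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class TRNAReference:
    """Ordered, id-indexed collection of :class:`TRNASpecies`."""

    species: list[TRNASpecies] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [sp.id for sp in self.species]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate species ids: {sorted(dupes)}")
        self._index = {sp.id: sp for sp in self.species}

    def __len__(self) -> int:
        return len(self.species)

    def __iter__(self) -> Iterator[TRNASpecies]:
        return iter(self.species)

    def __contains__(self, species_id: str) -> bool:
        return species_id in self._index

    def __getitem__(self, species_id: str) -> TRNASpecies:
        return self._index[species_id]

    @property
    def ids(self) -> list[str]:
        return [sp.id for sp in self.species]

    @property
    def total_length(self) -> int:
        return sum(sp.length for sp in self.species)


def load_reference(fasta_path: str | Path, annotation_path: str | Path) -> TRNAReference:
    """Load and validate a tRNA reference from FASTA + annotation TSV.

    DNA input (``T``) is transcribed to ``U``.  Duplicate ids and annotated m7G
    positions that do not point at a guanosine are hard errors naming the
    offending record.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate species ids: ['{rec.id}']")
        seqs[rec.id] = str(rec.seq).upper().replace("T", "U")

    ann = pd.read_csv(annotation_path, sep="\t", dtype={"id": str})
    required = {"id", "amino_acid", "anticodon", "m7g_pos", "var_loop_start", "var_loop_end"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    if ann["id"].duplicated().any():
        raise ValueError(
            f"duplicate species ids: {sorted(ann.loc[ann['id'].duplicated(), 'id'])}"
        )
    unknown = set(ann["id"]) - set(seqs)
    if unknown:
        raise ValueError(f"annotation ids without FASTA record: {sorted(unknown)}")

    species = []
    for row in ann.itertuples():
        m7g = None if pd.isna(row.m7g_pos) else int(row.m7g_pos)
        species.append(
            TRNASpecies(
                id=row.id,
                amino_acid=str(row.amino_acid),
                anticodon=str(row.anticodon).upper().replace("T", "U"),
                sequence=seqs[row.id],
                m7g_pos=m7g,
                var_loop=(int(row.var_loop_start), int(row.var_loop_end)),
            )
        )
    ref = TRNAReference(species)
    if len(ref) == 0:
        raise ValueError("empty reference")
    return ref


def write_reference(
    ref: TRNAReference, fasta_path: str | Path, annotation_path: str | Path
) -> None:
    """Write a reference as FASTA + annotation TSV (exact round-trip of ``load_reference``)."""
    records = [
        SeqRecord(Seq(sp.sequence), id=sp.id, description="") for sp in ref
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = [
        {
            "id": sp.id,
            "amino_acid": sp.amino_acid,
            "anticodon": sp.anticodon,
            "m7g_pos": sp.m7g_pos,
            "var_loop_start": sp.var_loop[0],
            "var_loop_end": sp.var_loop[1],
        }
        for sp in ref
    ]
    pd.DataFrame(rows).to_csv(annotation_path, sep="\t", index=False)


def g46_subset(ref: TRNAReference) -> TRNAReference:
    """Species with an annotated variable-loop guanosine, in original order.

    The m7G-methylated position corresponds to Sprinzl position 46 in full-size
    tRNAs, but each species carries its own annotated index; this filter is the
    in-package analogue of restricting a heatmap to the tRNAs with a guanosine
    at that position.  Idempotent; may return an empty reference.
    """
    return TRNAReference([sp for sp in ref if sp.m7g_pos is not None])


def reference_summary(ref: TRNAReference) -> pd.DataFrame:
    """User-facing summary table (1-based closed coordinates)."""
    rows = []
    for sp in ref:
        rows.append(
            {
                "id": sp.id,
                "amino_acid": sp.amino_acid,
                "anticodon": sp.anticodon,
                "length": sp.length,
                "m7g_pos_1based": None if sp.m7g_pos is None else sp.m7g_pos + 1,
                "var_loop_1based": f"{sp.var_loop[0] + 1}-{sp.var_loop[1]}",
            }
        )
    return pd.DataFrame(rows)
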