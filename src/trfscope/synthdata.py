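"""Synthetic inputs with the statistical structure the analyses assume.

Every stage of the pipeline can be exercised without downloads: this module
generates a toy mature-tRNA reference with annotated variable-loop guanosines,
small-RNA read mixtures with knockout-specific 5' terminal-oligoguanine (5'TOG)
fragment excess, aniline-cleavage 5'-end profiles with wild-type-specific peaks
at the annotated m7G site, multi-cohort expression matrices with planted
differential genes, and polysome fraction tables with planted shifts.

Randomness: one integer seed drives named per-purpose streams
(:func:`rng_stream`), so adding a new simulated quantity does not perturb the
draws of existing ones.  Counts are negative-binomial with the
variance = mu + alpha * mu**2 parameterisation, matching the convention the
differential-abundance module estimates.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cleavage import CleavageProfile
from .reference import TRNAReference, TRNASpecies
from .screens import ExpressionCohort, PolysomeProfile

__all__ = [
    "rng_stream",
    "nb_sample",
    "make_trna_reference",
    "PlantedTOG",
    "FragmentDesign",
    "simulate_fragment_reads",
    "CleavageDesign",
    "simulate_cleavage_profiles",
    "PlantedGene",
    "CohortDesign",
    "simulate_expression_cohorts",
    "simulate_polysome_profile",
]

# Cys first (gives rise to 5G 5'TOGs), Ala second (4G); the rest are fillers.
_AMINO_ACIDS = ["Cys", "Ala", "Lys", "Pro", "Phe", "Gly", "Glu", "His", "Ile", "Val"]
_ANTICODONS = ["GCA", "AGC", "CUU", "AGG", "GAA", "GCC", "CUC", "GUG", "AAU", "AAC"]


def rng_stream(seed: int, purpose: str) -> np.random.Generator:
    """Independent generator derived from a global seed and a purpose name."""
    key = zlib.crc32(purpose.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


def nb_sample(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative-binomial draws with variance = mu + dispersion * mu**2.

    ``dispersion == 0`` degenerates to Poisson.  Implemented as a
    gamma-mixed Poisson, which is exact for this parameterisation.
    """
    mu = np.asarray(mu, dtype=float)
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if dispersion == 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = np.where(mu > 0, rng.gamma(shape, np.maximum(mu, 1e-300) * dispersion), 0.0)
    return rng.poisson(lam)


def make_trna_reference(
    n_species: int,
    n_m7g_targets: int,
    length: int = 76,
    seed: int = 0,
) -> TRNAReference:
    """Random toy tRNA reference with fixed structural scaffolding.

    Every species carries a 7-nt acceptor-stem prefix, an anticodon, a terminal
    CCA, and a 5-nt variable-loop interval near the 3' end.  The first
    ``n_m7g_targets`` species get a guanosine planted inside the variable loop
    and recorded as ``m7g_pos`` (the toy analogue of Sprinzl position 46).  The
    first two species are the designated 5'TOG sources and begin with five
    (Cys-like) or four (Ala-like) terminal guanosines.
    """
    if n_m7g_targets > n_species:
        raise ValueError("n_m7g_targets must be <= n_species")
    if length < 60:
        raise ValueError(f"length {length} too short to host the tRNA scaffold (>=60)")
    rng = rng_stream(seed, "make_trna_reference")
    var_start, var_end = length - 32, length - 27
    anticodon_start = min(33, var_start - 4)
    species = []
    for i in range(n_species):
        aa = _AMINO_ACIDS[i % len(_AMINO_ACIDS)]
        anticodon = _ANTICODONS[i % len(_ANTICODONS)]
        seq = rng.choice(list("ACGU"), size=length).tolist()
        # 5' terminal G run for the TOG-source species: Cys-like 5G, Ala-like 4G
        if i == 0:
            seq[:5] = list("GGGGG")
        elif i == 1:
            seq[:4] = list("GGGG")
            if seq[4] == "G":  # keep the run at exactly 4
                seq[4] = "A"
        seq[anticodon_start : anticodon_start + 3] = list(anticodon)
        m7g_pos: Optional[int] = None
        if i < n_m7g_targets:
            m7g_pos = var_start + 1
            seq[m7g_pos] = "G"
        seq[-3:] = list("CCA")
        species.append(
            TRNASpecies(
                id=f"{aa}-{anticodon}-sim{i}",
                amino_acid=aa,
                anticodon=anticodon,
                sequence="".join(seq),
                m7g_pos=m7g_pos,
                var_loop=(var_start, var_end),
            )
        )
    return TRNAReference(species)


@dataclass(frozen=True)
class PlantedTOG:
    """A knockout-enriched 5'-anchored terminal-oligoguanine fragment family."""

    species_id: str
    lengths: tuple[int, ...] = (20, 30)
    min_g: int = 4
    log2_excess: float = 3.0
    wt_mean_fraction: float = 0.002  # expected WT share of library depth per fragment

    def __post_init__(self) -> None:
        for ell in self.lengths:
            if not 18 <= ell <= 50:
                raise ValueError(f"planted fragment length {ell} outside [18, 50]")


@dataclass
class FragmentDesign:
    """Design of a simulated small-RNA fragment experiment."""

    conditions: dict[str, int] = field(default_factory=lambda: {"WT": 3, "KO": 3})
    depth_per_sample: int = 50_000
    full_length_fraction: float = 0.35
    planted_togs: tuple[PlantedTOG, ...] = ()
    background_cleavage_rate: float = 0.05
    nb_dispersion: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.full_length_fraction <= 1.0:
            raise ValueError("full_length_fraction must be in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if any(n < 2 for n in self.conditions.values()):
            raise ValueError("replicate counts must be >= 2 per condition")
        planted_mass = sum(
            t.wt_mean_fraction * len(t.lengths) for t in self.planted_togs
        )
        if planted_mass > 1.0 - self.full_length_fraction + 1e-12:
            raise ValueError(
                "planted 5'TOG mass exceeds the non-full-length fraction of the library"
            )

    @property
    def sample_names(self) -> list[str]:
        return [
            f"{cond}_{r + 1}" for cond, n in self.conditions.items() for r in range(n)
        ]


def _fragment_catalogue(
    ref: TRNAReference, design: FragmentDesign, rng: np.random.Generator
) -> list[tuple[str, float, float]]:
    """(sequence, WT mean, KO mean) per fragment type; means sum to ~depth."""
    depth = design.depth_per_sample
    catalogue: list[tuple[str, float, float]] = []

    # full-length molecules, random species weights
    if design.full_length_fraction > 0 and len(ref) > 0:
        w = rng.dirichlet(np.full(len(ref), 5.0))
        for sp, wi in zip(ref, w):
            mu = depth * design.full_length_fraction * wi
            catalogue.append((sp.sequence, mu, mu))

    # planted 5'-anchored TOG fragments with KO excess
    planted_mass = 0.0
    for tog in design.planted_togs:
        if tog.species_id not in ref:
            raise ValueError(f"planted TOG species {tog.species_id!r} not in reference")
        sp = ref[tog.species_id]
        run = len(sp.sequence) - len(sp.sequence.lstrip("G"))
        if run < tog.min_g:
            raise ValueError(
                f"species {sp.id!r} lacks a 5'-terminal G run >= {tog.min_g} "
                f"(has {run})"
            )
        for ell in tog.lengths:
            mu_wt = depth * tog.wt_mean_fraction
            catalogue.append((sp.sequence[:ell], mu_wt, mu_wt * 2.0**tog.log2_excess))
            planted_mass += tog.wt_mean_fraction

    # background cleavage: each interior position is a single-hit cut site with
    # probability background_cleavage_rate, yielding a 5' and a 3' piece
    bg_mass = max(0.0, 1.0 - design.full_length_fraction - planted_mass)
    bg_frags: list[str] = []
    for sp in ref:
        cuts = np.flatnonzero(
            rng.random(sp.length - 1) < design.background_cleavage_rate
        ) + 1
        for p in cuts:
            for frag in (sp.sequence[:p], sp.sequence[p:]):
                if len(frag) < sp.length:
                    bg_frags.append(frag)
    if bg_frags and bg_mass > 0:
        w = rng.dirichlet(np.ones(len(bg_frags)))
        for frag, wi in zip(bg_frags, w):
            mu = depth * bg_mass * wi
            catalogue.append((frag, mu, mu))
    return catalogue


def simulate_fragment_reads(
    ref: TRNAReference, design: FragmentDesign
) -> dict[str, list[str]]:
    """Per-sample small-RNA read collections.

    Reads are exact substrings of the reference (no sequencing errors); planted
    5'TOG fragments are 5'-anchored and carry a ``2**log2_excess``-fold KO mean.
    Per-fragment, per-sample counts are NB(mu * libsize_factor, nb_dispersion);
    library-size factors vary by less than 2x across samples.
    """
    rng = rng_stream(design.seed, "simulate_fragment_reads")
    if design.depth_per_sample == 0:
        return {s: [] for s in design.sample_names}
    catalogue = _fragment_catalogue(ref, design, rng)
    lib_factors = rng.uniform(0.75, 1.35, size=len(design.sample_names))
    reads: dict[str, list[str]] = {}
    i = 0
    for cond, n_reps in design.conditions.items():
        ko_like = cond != "WT"
        for _ in range(n_reps):
            sample = design.sample_names[i]
            mus = np.array(
                [(mu_ko if ko_like else mu_wt) for _, mu_wt, mu_ko in catalogue]
            )
            counts = nb_sample(rng, mus * lib_factors[i], design.nb_dispersion)
            sample_reads: list[str] = []
            for (frag, _, _), c in zip(catalogue, counts):
                sample_reads.extend([frag] * int(c))
            reads[sample] = sample_reads
            i += 1
    return reads


@dataclass
class CleavageDesign:
    """Design of a simulated aniline-cleavage (5'-end profile) experiment."""

    conditions: dict[str, int] = field(default_factory=lambda: {"WT": 2, "KO": 2})
    depth_per_species: int = 10_000
    signal_fraction: float = 0.3
    ko_signal_fraction: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ko_signal_fraction < self.signal_fraction <= 1.0:
            raise ValueError("need 0 <= ko_signal_fraction < signal_fraction <= 1")


def simulate_cleavage_profiles(
    ref: TRNAReference, design: CleavageDesign, offset: int = 1
) -> list[CleavageProfile]:
    """Multinomial 5'-end count profiles per species, condition and replicate.

    For species with an annotated m7G, WT concentrates ``signal_fraction`` of
    the 5' ends at ``m7g_pos + offset`` (the scission registers one position
    downstream of the methylated guanosine); KO retains only
    ``ko_signal_fraction``.  Unannotated species receive uniform background.
    """
    if len(ref) == 0:
        raise ValueError("empty reference")
    rng = rng_stream(design.seed, "simulate_cleavage_profiles")
    profiles = []
    for sp in ref:
        length = sp.length
        for cond, n_reps in design.conditions.items():
            if sp.m7g_pos is not None:
                peak = (
                    design.signal_fraction
                    if cond == "WT"
                    else design.ko_signal_fraction
                )
            else:
                peak = 0.0
            probs = np.full(length, (1.0 - peak) / length)
            if peak > 0:
                probs[sp.m7g_pos + offset] += peak
            for r in range(n_reps):
                counts = rng.multinomial(design.depth_per_species, probs)
                profiles.append(
                    CleavageProfile(
                        species_id=sp.id,
                        condition=cond,
                        replicate=f"{cond}_{r + 1}",
                        counts=counts,
                    )
                )
    return profiles


@dataclass(frozen=True)
class PlantedGene:
    """A gene with a planted group-mean shift in a fraction of cohorts."""

    gene: str
    effect_sd: float = 2.0
    groups: tuple[str, ...] = ("P", "M")
    cohort_fraction: float = 1.0


@dataclass
class CohortDesign:
    """Design of a set of synthetic expression cohorts (log2 scale)."""

    n_cohorts: int = 5
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"N": 10, "P": 10, "M": 10}
    )
    n_genes: int = 200
    planted: tuple[PlantedGene, ...] = ()
    baseline_mean: float = 8.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group_sizes.get("N", 0) < 2:
            raise ValueError("need >=2 N samples per cohort")
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 2")


def simulate_expression_cohorts(design: CohortDesign) -> list[ExpressionCohort]:
    """Cohorts of null genes ~ Normal(mu_gene, noise_sd) plus planted shifts.

    Planted genes are shifted by ``effect_sd`` (in noise-SD units) in the
    designated tumour groups in the first ``round(cohort_fraction * n_cohorts)``
    cohorts.
    """
    rng = rng_stream(design.seed, "simulate_expression_cohorts")
    genes = [f"G{i:04d}" for i in range(design.n_genes)]
    for pg in design.planted:
        if pg.gene not in genes:
            genes.append(pg.gene)
    base_mu = design.baseline_mean + rng.normal(0.0, 1.0, size=len(genes))
    labels = [g for g, n in design.group_sizes.items() for _ in range(n)]
    cohorts = []
    for k in range(design.n_cohorts):
        cols = [f"S{j:03d}" for j in range(len(labels))]
        expr = pd.DataFrame(
            base_mu[:, None] + rng.normal(0.0, design.noise_sd, (len(genes), len(cols))),
            index=genes,
            columns=cols,
        )
        for pg in design.planted:
            if k < round(pg.cohort_fraction * design.n_cohorts):
                for grp in pg.groups:
                    grp_cols = [c for c, g in zip(cols, labels) if g == grp]
                    expr.loc[pg.gene, grp_cols] += pg.effect_sd * design.noise_sd
        cohorts.append(ExpressionCohort(name=f"cohort{k + 1}", expr=expr, labels=labels))
    return cohorts


def simulate_polysome_profile(
    n_transcripts: int,
    n_fractions: int = 16,
    shifted: Sequence[str] = (),
    shift_mass: float = 0.35,
    n_polysome: int = 6,
    depth_per_transcript: int = 10_000,
    seed: int = 0,
) -> PolysomeProfile:
    """Polysome fraction table with optional planted shifts into polysome fractions.

    Unshifted transcripts concentrate mass in the early (sub-polysomal)
    fractions with an exponential decay; transcripts named in ``shifted`` move
    ``shift_mass`` of their total into the last ``n_polysome`` fractions.
    """
    if n_fractions < 4:
        raise ValueError("need >=4 fractions")
    if not 0 <= n_polysome < n_fractions:
        raise ValueError("n_polysome must be in [0, n_fractions)")
    rng = rng_stream(seed, "simulate_polysome_profile")
    transcripts = [f"T{i:04d}" for i in range(n_transcripts)]
    for t in shifted:
        if t not in transcripts:
            transcripts.append(t)
    mask = np.zeros(n_fractions, dtype=bool)
    mask[n_fractions - n_polysome :] = True
    base = np.exp(-np.arange(n_fractions) / 2.0)
    base /= base.sum()
    rows = []
    for t in transcripts:
        shares = base.copy()
        if t in shifted:
            poly0 = shares[mask].sum()
            target = min(poly0 + shift_mass, 0.999)
            shares[mask] *= target / poly0
            shares[~mask] *= (1.0 - target) / (1.0 - poly0)
        rows.append(rng.poisson(shares * depth_per_transcript))
    abundance = pd.DataFrame(
        rows, index=transcripts, columns=[f"F{j + 1}" for j in range(n_fractions)]
    )
    return PolysomeProfile(abundance=abundance, polysome_mask=mask)
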