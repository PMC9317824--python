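"""Qualification of annotated variants for gene-burden testing.

A burden test only collapses *qualifying* variants.  Two classes qualify:

* **Loss-of-function (LoF)** — stop-gain or frameshift variants, unless they
  truncate only the final tail of the coding sequence (by default the last
  5%, where truncation is unlikely to abolish protein function); splice-site
  variants; and variants that abolish translation initiation (start-lost).
* **Rare deleterious missense** — missense variants below a minor-allele
  frequency (MAF) ceiling whose precomputed deleteriousness score (e.g. a
  BayesDel-style combined score) reaches a configurable threshold.

Consequence classes and deleteriousness scores are inputs (annotations); the
module's job is to apply the qualification rules, including the coding-
sequence (CDS) position arithmetic behind the tail-truncation exclusion.

All coordinates are 1-based inclusive, following VCF convention.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Consequence",
    "Variant",
    "TranscriptModel",
    "QualificationParams",
    "NOT_IN_CDS",
    "compute_cds_fraction",
    "qualify_lof",
    "qualify_missense",
    "compute_maf",
    "build_variant_sets",
]


class Consequence(str, enum.Enum):
    """Functional consequence class of an alternate allele."""

    STOP_GAINED = "stop_gained"
    FRAMESHIFT = "frameshift"
    SPLICE_SITE = "splice_site"
    START_LOST = "start_lost"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: Truncating consequences for which the CDS-tail exclusion applies.
TRUNCATING = frozenset({Consequence.STOP_GAINED, Consequence.FRAMESHIFT})


@dataclass
class Variant:
    """One annotated alternate allele.

    Parameters
    ----------
    chrom, pos : str, int
        Reference coordinate, 1-based.
    ref, alt : str
        Allele strings (one ALT per variant; multi-allelic records must be
        split upstream).
    gene_id : str
        Gene the allele is annotated to.
    consequence : Consequence
        Predicted functional class.
    delscore : float or None
        Precomputed deleteriousness score for missense variants; ``None``
        when unscored.
    maf : float or None
        Folded minor-allele frequency in [0, 0.5]; computed from the cohort
        or supplied externally.
    cds_fraction : float or None
        5'→3' position within the coding sequence as a fraction of total CDS
        length, when the variant overlaps a CDS.
    af_ext : float or None
        Optional external (reference-population) alternate-allele frequency;
        can replace the cohort-computed MAF during qualification.
    transcript_ids : sequence of str
        Transcripts the annotation refers to (informational).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str
    consequence: Consequence
    delscore: float | None = None
    maf: float | None = None
    cds_fraction: float | None = None
    af_ext: float | None = None
    transcript_ids: Sequence[str] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        self.consequence = Consequence(self.consequence)
        if self.maf is not None and not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"maf must lie in [0, 0.5], got {self.maf}")

    @property
    def key(self) -> str:
        """Canonical variant key ``chrom:pos:ref:alt``."""
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class TranscriptModel:
    """Coding-sequence model of one transcript.

    ``cds_intervals`` are 1-based inclusive genomic intervals, sorted
    ascending and disjoint.  On the minus strand the *last* genomic interval
    contains the first coding base.
    """

    transcript_id: str
    gene_id: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        ivals = tuple(tuple(iv) for iv in self.cds_intervals)
        if not ivals:
            raise ValueError("transcript must have at least one CDS interval")
        prev_end = 0
        for start, end in ivals:
            if start > end:
                raise ValueError(f"interval {start}-{end} is reversed")
            if start <= prev_end:
                raise ValueError("CDS intervals must be sorted and disjoint")
            prev_end = end
        object.__setattr__(self, "cds_intervals", ivals)

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.cds_intervals)


@dataclass
class QualificationParams:
    """Thresholds controlling variant qualification.

    ``delscore_min`` has no default: the deleteriousness threshold depends on
    the score in use and must be chosen explicitly.
    """

    delscore_min: float
    maf_max: float = 0.01
    cds_tail_fraction: float = 0.05
    splice_window: int = 2

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_max <= 0.5):
            raise ValueError(f"maf_max must lie in (0, 0.5], got {self.maf_max}")
        if not (0.0 <= self.cds_tail_fraction < 1.0):
            raise ValueError(
                f"cds_tail_fraction must lie in [0, 1), got {self.cds_tail_fraction}"
            )
        if self.splice_window < 0:
            raise ValueError("splice_window must be non-negative")


class _NotInCds:
    """Sentinel: position does not fall in the transcript's CDS."""

    def __repr__(self) -> str:  # pragma: no cover
        return "NOT_IN_CDS"

    def __bool__(self) -> bool:
        return False


NOT_IN_CDS = _NotInCds()


def compute_cds_fraction(pos: int, transcript: TranscriptModel):
    """Fractional 5'→3' coding position of ``pos`` within a transcript.

    Returns the number of coding bases at or 5' of ``pos`` (in transcript
    orientation) divided by the CDS length, a value in (0, 1].  The first
    coding base of a 100-bp CDS maps to 0.01, the last to 1.0.  On the minus
    strand genomic order is reversed.

    Returns :data:`NOT_IN_CDS` when ``pos`` lies outside every CDS interval.
    """
    upstream = 0  # coding bases genomically 5' of pos, inclusive
    inside = False
    for start, end in transcript.cds_intervals:
        if pos > end:
            upstream += end - start + 1
        elif pos >= start:
            upstream += pos - start + 1
            inside = True
            break
        else:
            break
    if not inside:
        return NOT_IN_CDS
    length = transcript.cds_length
    if transcript.strand == "+":
        rank = upstream
    else:
        rank = length - upstream + 1
    return rank / length


def is_near_exon_boundary(
    pos: int, transcript: TranscriptModel, window: int = 2
) -> bool:
    """Whether ``pos`` lies within ``window`` bases of an internal CDS
    interval boundary (the operational splice-region check; terminal CDS ends
    facing the UTRs are not splice junctions)."""
    ivals = transcript.cds_intervals
    boundaries: list[int] = []
    for i, (start, end) in enumerate(ivals):
        if i > 0:
            boundaries.append(start)
        if i < len(ivals) - 1:
            boundaries.append(end)
    return any(abs(pos - b) <= window for b in boundaries)


def compute_maf(allele_counts: Iterable[int], ploidy: int = 2):
    """Folded minor-allele frequency from per-sample alternate-allele counts.

    ``allele_counts`` holds 0/1/2 alternate-allele dosages for diploid
    samples; negative entries denote missing genotypes and are removed from
    the denominator.  Returns ``min(p, 1 - p)`` where ``p`` is the alternate
    allele frequency over called alleles, or ``None`` when every genotype is
    missing.
    """
    ac = np.asarray(list(allele_counts) if not isinstance(allele_counts, np.ndarray) else allele_counts)
    called = ac >= 0
    n_alleles = int(called.sum()) * ploidy
    if n_alleles == 0:
        return None
    p = float(ac[called].sum()) / n_alleles
    return min(p, 1.0 - p)


def qualify_lof(
    variant: Variant,
    transcripts: Sequence[TranscriptModel] = (),
    params: QualificationParams | None = None,
) -> tuple[bool, str]:
    """Apply the loss-of-function qualification rules to one variant.

    Returns ``(qualifies, reason)`` where ``reason`` names the clause that
    decided the outcome:

    ``truncating``
        stop-gain/frameshift with CDS fraction at or before the tail cutoff;
    ``cds_tail``
        truncating but confined to the excluded CDS tail;
    ``splice_site`` / ``start_lost``
        the respective consequence clauses;
    ``common`` / ``class`` / ``unresolvable`` / ``no_maf``
        disqualifying outcomes (MAF at or above the ceiling, a non-LoF
        consequence class, a truncating variant whose CDS position cannot be
        resolved, or a variant with no MAF at all).

    For truncating variants the CDS fraction is evaluated on the supplied
    transcripts of the variant's gene, taking the transcript giving the most
    severe outcome (smallest fraction); a pre-set ``variant.cds_fraction`` is
    used when no transcript covers the position.
    """
    if params is None:
        raise ValueError("params is required")
    csq = variant.consequence
    if csq not in TRUNCATING and csq not in (
        Consequence.SPLICE_SITE,
        Consequence.START_LOST,
    ):
        return False, "class"
    if variant.maf is None:
        return False, "no_maf"
    if variant.maf >= params.maf_max:
        return False, "common"

    if csq is Consequence.SPLICE_SITE:
        return True, "splice_site"
    if csq is Consequence.START_LOST:
        return True, "start_lost"

    # truncating: need a CDS position to apply the tail exclusion
    fractions = []
    for tx in transcripts:
        if tx.gene_id != variant.gene_id:
            continue
        frac = compute_cds_fraction(variant.pos, tx)
        if frac is not NOT_IN_CDS:
            fractions.append(frac)
    if not fractions and variant.cds_fraction is not None:
        fractions.append(variant.cds_fraction)
    if not fractions:
        return False, "unresolvable"
    frac = min(fractions)
    if frac > 1.0 - params.cds_tail_fraction:
        return False, "cds_tail"
    return True, "truncating"


def qualify_missense(
    variant: Variant, params: QualificationParams
) -> tuple[bool, str]:
    """Apply the rare-deleterious-missense rules to one variant.

    Qualifies iff the variant is missense, carries a deleteriousness score at
    or above ``params.delscore_min``, and has MAF below ``params.maf_max``.
    """
    if variant.consequence is not Consequence.MISSENSE:
        return False, "class"
    if variant.delscore is None:
        return False, "unscored"
    if variant.maf is None:
        return False, "no_maf"
    if variant.maf >= params.maf_max:
        return False, "common"
    if variant.delscore < params.delscore_min:
        return False, "benign_score"
    return True, "deleterious_missense"


@dataclass
class VariantSets:
    """Qualifying variant keys of one gene, by class."""

    lof: set[str] = field(default_factory=set)
    missense: set[str] = field(default_factory=set)

    @property
    def combined(self) -> set[str]:
        return self.lof | self.missense


def build_variant_sets(
    variants: Sequence[Variant],
    transcripts: Sequence[TranscriptModel],
    params: QualificationParams,
    report: list | None = None,
    use_external_af: bool = False,
) -> Mapping[str, VariantSets]:
    """Qualify every variant and group the survivors per gene and class.

    Returns a mapping ``gene_id -> VariantSets``; the ``combined`` class is
    the union of the disjoint LoF and missense sets.  When ``report`` is
    given, one ``(variant_key, gene, class, qualifies, reason)`` tuple is
    appended per variant for the qualification report.  With
    ``use_external_af`` a variant's external allele frequency, when present,
    replaces the cohort-computed MAF (folded).
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tx in transcripts:
        by_gene.setdefault(tx.gene_id, []).append(tx)

    sets: dict[str, VariantSets] = {}
    for v in variants:
        if use_external_af and v.af_ext is not None:
            v = Variant(
                chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                gene_id=v.gene_id, consequence=v.consequence,
                delscore=v.delscore, maf=min(v.af_ext, 1.0 - v.af_ext),
                cds_fraction=v.cds_fraction, af_ext=v.af_ext,
                transcript_ids=v.transcript_ids,
            )
        txs = by_gene.get(v.gene_id, [])
        ok_lof, reason = qualify_lof(v, txs, params)
        klass = "lof"
        if not ok_lof and v.consequence is Consequence.MISSENSE:
            ok_mis, reason = qualify_missense(v, params)
            klass = "missense"
            if ok_mis:
                sets.setdefault(v.gene_id, VariantSets()).missense.add(v.key)
        elif ok_lof:
            sets.setdefault(v.gene_id, VariantSets()).lof.add(v.key)
        qualified = ok_lof or (klass == "missense" and reason == "deleterious_missense")
        if report is not None:
            report.append((v.key, v.gene_id, klass if qualified else "none", qualified, reason))
    return sets
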