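"""Post-calling somatic variant filters and germline candidate selection.

Exome tumor/normal calls from FFPE-derived material carry two prominent
artifact classes: C>T transitions from cytosine deamination and C>A
transversions from oxidative damage (8-oxoG), both concentrated at low
variant allele frequency (VAF).  The filters here remove those artifact
classes with coverage-stratified VAF thresholds, apply general depth/VAF
filtering against residual noise and germline leakage, and drop common
population variants.  A separate selector picks candidate germline risk
alleles: rare truncating variants in genes one-to-one orthologous to a
Cancer Gene Census (CGC) gene.

All filters are pure functions over lists of :class:`SomaticVariant`, return
``(kept, removed, report)`` and never mutate their input, so they compose in
any order and are idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "SomaticVariant",
    "FilterReport",
    "deamination_filter",
    "oxidative_artifact_filter",
    "general_filter",
    "common_variant_filter",
    "apply_filters",
    "germline_candidates",
    "mutation_rate",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: consequence strings treated as protein-truncating for germline selection
TRUNCATING_CONSEQUENCES = frozenset({"frameshift", "nonsense"})


@dataclass(frozen=True)
class SomaticVariant:
    """One tumor/normal-matched variant call.

    Coordinates are 1-based; ``ref``/``alt`` follow VCF conventions for the
    variant class (SNV: single base each; INS/DEL: anchored alleles or bare
    inserted/deleted sequence, as produced by the parser).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str  # SNV | MNV | INS | DEL
    tumor_depth: int
    tumor_alt: int
    normal_depth: int
    normal_alt: int
    sample_id: str
    population_af: float | None = None
    consequence: str | None = None
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.tumor_alt > self.tumor_depth:
            raise ValueError(
                f"tumor_alt ({self.tumor_alt}) > tumor_depth ({self.tumor_depth}) "
                f"at {self.chrom}:{self.pos}"
            )
        if self.normal_alt > self.normal_depth:
            raise ValueError(
                f"normal_alt ({self.normal_alt}) > normal_depth ({self.normal_depth}) "
                f"at {self.chrom}:{self.pos}"
            )
        if min(self.tumor_depth, self.tumor_alt, self.normal_depth, self.normal_alt) < 0:
            raise ValueError(f"negative read count at {self.chrom}:{self.pos}")

    @property
    def tumor_vaf(self) -> float:
        """Tumor VAF; 0.0 for zero depth (callers guard depth separately)."""
        return self.tumor_alt / self.tumor_depth if self.tumor_depth > 0 else 0.0

    @property
    def normal_vaf(self) -> float:
        return self.normal_alt / self.normal_depth if self.normal_depth > 0 else 0.0

    def is_substitution(self, ref: str, alt: str) -> bool:
        return self.variant_class == "SNV" and self.ref == ref and self.alt == alt


@dataclass
class FilterReport:
    """Bookkeeping for a chain of filters: per-filter removed/retained counts."""

    steps: list[dict] = field(default_factory=list)

    def record(self, name: str, n_input: int, n_kept: int, n_removed: int) -> None:
        if n_kept + n_removed != n_input:
            raise ValueError(
                f"filter {name!r} does not conserve counts: "
                f"{n_kept} + {n_removed} != {n_input}"
            )
        self.steps.append(
            {"filter": name, "input": n_input, "kept": n_kept, "removed": n_removed}
        )

    @property
    def filters_applied(self) -> list[str]:
        return [s["filter"] for s in self.steps]

    def to_rows(self) -> list[dict]:
        return [dict(s) for s in self.steps]


def _fails_artifact_thresholds(v: SomaticVariant) -> bool:
    # Shared coverage-stratified VAF rule for deamination/oxidative artifacts:
    # remove if VAF < 0.1, or tumor coverage < 20x, or coverage 20-99x with
    # VAF < 0.2.  Coverage >= 100x requires only VAF >= 0.1.
    vaf = v.tumor_vaf
    if vaf < 0.1:
        return True
    if v.tumor_depth < 20:
        return True
    if 20 <= v.tumor_depth <= 99 and vaf < 0.2:
        return True
    return False


def _split(
    variants: Iterable[SomaticVariant], remove_pred, name: str, report: FilterReport | None
) -> tuple[list[SomaticVariant], list[SomaticVariant], FilterReport]:
    variants = list(variants)
    report = report if report is not None else FilterReport()
    removed = [v for v in variants if remove_pred(v)]
    kept = [v for v in variants if not remove_pred(v)]
    report.record(name, len(variants), len(kept), len(removed))
    return kept, removed, report


def deamination_filter(
    variants: Sequence[SomaticVariant], report: FilterReport | None = None
) -> tuple[list[SomaticVariant], list[SomaticVariant], FilterReport]:
    """Remove low-VAF C>T / G>A deamination artifacts.

    A C>T (or G>A) SNV is removed iff its tumor VAF is < 0.1, its tumor
    coverage is < 20x, or the coverage is 20-99x and the VAF is < 0.2.
    Non-C>T/G>A variants (including MNVs and indels) pass untouched.

    Raises ``ValueError`` if a candidate C>T/G>A SNV has zero tumor depth.
    """
    for v in variants:
        if (v.is_substitution("C", "T") or v.is_substitution("G", "A")) and v.tumor_depth == 0:
            raise ValueError(
                f"malformed candidate with zero tumor depth at {v.chrom}:{v.pos}"
            )

    def pred(v: SomaticVariant) -> bool:
        if not (v.is_substitution("C", "T") or v.is_substitution("G", "A")):
            return False
        return _fails_artifact_thresholds(v)

    return _split(variants, pred, "deamination", report)


def oxidative_artifact_filter(
    variants: Sequence[SomaticVariant],
    genome,
    report: FilterReport | None = None,
) -> tuple[list[SomaticVariant], list[SomaticVariant], FilterReport]:
    """Remove low-VAF C>A / G>T oxidative-damage artifacts in CCN/TCN context.

    Applies the same coverage-stratified VAF thresholds as
    :func:`deamination_filter`, but only to C>A SNVs whose 5' reference base
    is C or T (equivalently G>T SNVs whose 3' base is G or A, i.e. NGG/NGA
    contexts on the opposite strand).

    ``genome`` is any mapping-like reference accessor supporting
    ``genome[chrom][start:end]`` with 0-based slices returning an object whose
    ``str()`` is the sequence (a ``pyfaidx.Fasta`` or a plain dict of strings).

    Variants whose context cannot be retrieved (contig edge, missing
    sequence) are kept and listed in the report step under ``warnings``.
    """
    variants = list(variants)
    report = report if report is not None else FilterReport()
    kept: list[SomaticVariant] = []
    removed: list[SomaticVariant] = []
    warnings: list[str] = []

    for v in variants:
        is_ca = v.is_substitution("C", "A")
        is_gt = v.is_substitution("G", "T")
        if not (is_ca or is_gt):
            kept.append(v)
            continue
        try:
            if is_ca:
                neighbour = str(genome[v.chrom][v.pos - 2 : v.pos - 1]).upper()  # 5' base
                in_context = neighbour in ("C", "T")
            else:
                neighbour = str(genome[v.chrom][v.pos : v.pos + 1]).upper()  # 3' base
                in_context = neighbour in ("G", "A")
            if neighbour == "" or neighbour not in "ACGTN":
                raise KeyError("empty or invalid context")
        except (KeyError, IndexError, ValueError):
            warnings.append(f"{v.chrom}:{v.pos} context unavailable; not filtered")
            kept.append(v)
            continue
        if in_context and _fails_artifact_thresholds(v):
            removed.append(v)
        else:
            kept.append(v)

    report.record("oxidative", len(variants), len(kept), len(removed))
    if warnings:
        report.steps[-1]["warnings"] = warnings
    return kept, removed, report


def general_filter(
    variants: Sequence[SomaticVariant], report: FilterReport | None = None
) -> tuple[list[SomaticVariant], list[SomaticVariant], FilterReport]:
    """Coverage/VAF filter applied to every variant class.

    A variant is kept iff tumor and normal depth are both >= 10x, the tumor
    VAF passes a coverage-stratified threshold (>= 0.1 below 300x coverage,
    >= 0.05 at 300x and above), and the VAF in the matched normal is < 0.01.
    """

    def pred(v: SomaticVariant) -> bool:
        if v.tumor_depth < 10 or v.normal_depth < 10:
            return True
        vaf = v.tumor_vaf
        if v.tumor_depth < 300:
            if vaf < 0.1:
                return True
        elif vaf < 0.05:
            return True
        return v.normal_vaf >= 0.01

    return _split(variants, pred, "general", report)


def common_variant_filter(
    variants: Sequence[SomaticVariant],
    population_db: Mapping[tuple, float],
    report: FilterReport | None = None,
    max_af: float = 0.01,
) -> tuple[list[SomaticVariant], list[SomaticVariant], FilterReport]:
    """Remove common population variants (population AF >= 1% by default).

    ``population_db`` maps ``(chrom, pos, ref, alt)`` to allele frequency.
    The variant's own ``population_af`` field is used as a fallback when the
    site is not in the database; sites unknown to both are kept (absence
    means rare).
    """

    def pred(v: SomaticVariant) -> bool:
        af = population_db.get((v.chrom, v.pos, v.ref, v.alt), v.population_af)
        return af is not None and af >= max_af

    return _split(variants, pred, "common_variant", report)


DEFAULT_FILTER_ORDER = ("common_variant", "deamination", "oxidative", "general")


def apply_filters(
    variants: Sequence[SomaticVariant],
    genome=None,
    population_db: Mapping[tuple, float] | None = None,
    order: Sequence[str] = DEFAULT_FILTER_ORDER,
) -> tuple[list[SomaticVariant], list[SomaticVariant], FilterReport]:
    """Run the post-calling filter chain in ``order``; returns (kept, removed, report)."""
    report = FilterReport()
    kept = list(variants)
    all_removed: list[SomaticVariant] = []
    for name in order:
        if name == "common_variant":
            kept, removed, report = common_variant_filter(
                kept, population_db or {}, report
            )
        elif name == "deamination":
            kept, removed, report = deamination_filter(kept, report)
        elif name == "oxidative":
            if genome is None:
                raise ValueError("oxidative filter requires a reference genome")
            kept, removed, report = oxidative_artifact_filter(kept, genome, report)
        elif name == "general":
            kept, removed, report = general_filter(kept, report)
        else:
            raise ValueError(f"unknown filter {name!r}")
        all_removed.extend(removed)
    return kept, all_removed, report


def germline_candidates(
    germline_variants: Sequence[SomaticVariant],
    ortholog_map: Mapping[str, str],
    cgc_genes: Iterable[str],
    genotyped_fraction: Mapping[tuple, float],
    multiallelic_sites: Iterable[tuple] = (),
    max_af: float = 0.001,
) -> list[SomaticVariant]:
    """Select candidate germline risk alleles.

    Keeps variants that are rare (population AF <= ``max_af`` or unknown),
    bi-allelic, genotyped in more than half of the cohort, protein-truncating
    (frameshift or nonsense), and whose gene is a one-to-one ortholog of a
    CGC gene.

    ``ortholog_map`` is a one-to-one mapping from this species' gene names to
    the partner species' (e.g. human) names; ``cgc_genes`` is the CGC set in
    the partner namespace.  ``genotyped_fraction`` maps ``(chrom, pos)`` to
    the fraction of cohort samples genotyped at the site (missing sites are
    assumed fully genotyped).  ``multiallelic_sites`` lists ``(chrom, pos)``
    keys to exclude.
    """
    missing = [v for v in germline_variants if v.consequence is None]
    if missing:
        loci = ", ".join(f"{v.chrom}:{v.pos}" for v in missing[:10])
        raise ValueError(f"missing consequence annotation for: {loci}")
    cgc = set(cgc_genes)
    multi = set(multiallelic_sites)
    out = []
    for v in germline_variants:
        if v.population_af is not None and v.population_af > max_af:
            continue
        if (v.chrom, v.pos) in multi:
            continue
        if genotyped_fraction.get((v.chrom, v.pos), 1.0) <= 0.5:
            continue
        if v.consequence not in TRUNCATING_CONSEQUENCES:
            continue
        if v.gene is None or ortholog_map.get(v.gene) not in cgc:
            continue
        out.append(v)
    return out


def mutation_rate(n_mutations: int, territory_bp: int) -> float:
    """Mutations per megabase over a sequencing territory."""
    if territory_bp <= 0:
        raise ValueError(f"territory_bp must be positive, got {territory_bp}")
    if n_mutations < 0:
        raise ValueError("n_mutations must be non-negative")
    return n_mutations / (territory_bp / 1e6)
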