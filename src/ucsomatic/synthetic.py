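"""Synthetic cohorts with known ground truth for every pipeline stage.

The generators emulate the structure of a cross-species tumor/normal exome
study at desk scale: a random reference genome with an exome annotation,
per-sample somatic variants drawn from known signature mixtures with
binomial read sampling at negative-binomial depth, low-VAF C>T deamination
artifacts injected at a configured rate, and per-chromosome copy-number
segment profiles with or without oscillating chromothripsis-like patterns.

The bundled truth signatures are synthetic stand-ins: ``pt_like_signature``
mimics the T>C / T>A-dominated spectrum of ptaquiloside (bracken fern)
mutagenesis, ``clock_like_signature`` the CpG deamination clock,
``mmr_like_signature`` / ``msi_like_signature`` mismatch-repair-deficiency
spectra, and ``flat_like_signature`` a featureless background.  They are not
COSMIC signatures; ``synthetic_reference_db`` exposes them under COSMIC-style
names purely so that reference-fitting code paths (e.g. the dMMR flag) can
be exercised without bundled external data.

All generators are reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ucsomatic.catalogs import (
    SBS96_CHANNELS,
    TRINUCLEOTIDES_32,
    channel_context,
    merge_intervals,
    revcomp,
)
from ucsomatic.copynumber import CnSegment
from ucsomatic.filtering import SomaticVariant
from ucsomatic.signatures import SignatureMatrix
from ucsomatic.strandbias import TranscriptAnnotation

__all__ = [
    "SimulationConfig",
    "ChromPlan",
    "generate_reference",
    "simulate_variants",
    "inject_artifacts",
    "simulate_cn_profiles",
    "pt_like_signature",
    "flat_like_signature",
    "clock_like_signature",
    "mmr_like_signature",
    "msi_like_signature",
    "synthetic_reference_db",
    "make_preset",
]

_COMP = str.maketrans("ACGT", "TGCA")


def _normalized(weights: Mapping[str, float]) -> pd.Series:
    s = pd.Series(0.0, index=list(SBS96_CHANNELS))
    for ch, w in weights.items():
        s[ch] = w
    total = s.sum()
    if total <= 0:
        raise ValueError("signature weights sum to zero")
    return s / total


def pt_like_signature() -> pd.Series:
    """Synthetic stand-in for an alkylation signature targeting adenines.

    On the pyrimidine strand this is T-centric: strong T>C at CTC/TTC,
    T>A at ATA/CTA/TTA, and minor T>G peaks, with essentially no C-channel
    activity.
    """
    weights: dict[str, float] = {}
    for ch in SBS96_CHANNELS:
        if ch[2] == "T":  # T-reference channels
            weights[ch] = 0.05
    weights.update(
        {
            "C[T>C]C": 14.0,
            "T[T>C]C": 12.0,
            "C[T>C]G": 3.0,
            "A[T>A]A": 8.0,
            "C[T>A]A": 7.0,
            "T[T>A]A": 6.0,
            "C[T>G]T": 3.0,
            "T[T>G]T": 2.0,
        }
    )
    return _normalized(weights)


def flat_like_signature() -> pd.Series:
    """Featureless background signature (mild, deterministic tilt)."""
    base = np.linspace(1.0, 1.4, len(SBS96_CHANNELS))
    return pd.Series(base / base.sum(), index=list(SBS96_CHANNELS))


def clock_like_signature() -> pd.Series:
    """Synthetic stand-in for the CpG-deamination clock: C>T at NCG.

    Support is restricted to C-reference channels, disjoint from the
    T-centric :func:`pt_like_signature`, so two-signature cohorts built from
    the pair are cleanly identifiable.
    """
    weights = {ch: 0.05 for ch in SBS96_CHANNELS if ch[2] == "C"}
    for five in "ACGT":
        weights[f"{five}[C>T]G"] = 10.0
    return _normalized(weights)


def mmr_like_signature() -> pd.Series:
    """Synthetic mismatch-repair-deficiency stand-in: broad C>T with G-5' bias."""
    weights = {ch: 0.03 for ch in SBS96_CHANNELS if ch[2] == "C"}
    for five in "ACGT":
        for three in "ACGT":
            weights[f"{five}[C>T]{three}"] = 2.0
    for three in "ACGT":
        weights[f"G[C>T]{three}"] = 6.0
    return _normalized(weights)


def msi_like_signature() -> pd.Series:
    """Second mismatch-repair stand-in: C>A/T>C mix distinct from the C>T one."""
    weights = {ch: 0.03 for ch in SBS96_CHANNELS}
    for three in "ACGT":
        weights[f"C[C>A]{three}"] = 4.0
        weights[f"A[T>C]{three}"] = 4.0
    return _normalized(weights)


def synthetic_reference_db() -> SignatureMatrix:
    """A small named reference signature set of synthetic stand-ins.

    The COSMIC-style names (SBS1, SBS5, SBS6, SBS44) are labels of
    convenience so that code driven by reference signature names — notably
    the dMMR flag's default MMR set — can be tested; the columns are the
    synthetic spectra defined in this module, not COSMIC data.
    """
    df = pd.DataFrame(
        {
            "SBS1": clock_like_signature(),
            "SBS5": flat_like_signature(),
            "SBS6": mmr_like_signature(),
            "SBS44": msi_like_signature(),
            "BF-A": pt_like_signature(),
        }
    )
    return SignatureMatrix(data=df, scheme="SBS96")


@dataclass(frozen=True)
class ChromPlan:
    """Copy-number plan for one chromosome of one sample."""

    chrom: str
    length_bp: int
    n_switches: int = 0
    states: tuple[int, ...] = (2, 3)
    baseline_cn: int = 2
    min_segment_bp: int = 200_000


@dataclass
class SimulationConfig:
    """Stated world for the synthetic cohort generators.

    Defaults describe a desk-scale exome cohort: two sub-megabase contigs at
    mammalian GC, ~30% exonic territory, 10 tumor/normal pairs at 100x mean
    tumor depth with clonal VAFs around 0.4 (purity-diluted heterozygous),
    and no artifacts unless ``artifact_rate`` is raised.
    """

    seed: int = 0
    contig_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 400_000, "chr2": 300_000}
    )
    gc_fraction: float = 0.42
    exon_length: int = 300
    exon_spacing: int = 1_000
    exons_per_transcript: int = 5
    n_samples: int = 10
    mutations_per_sample: int | Mapping[str, int] = 200
    signatures: SignatureMatrix | None = None
    exposures: pd.DataFrame | None = None  # samples x signatures, fractions
    artifact_rate: float = 0.0
    artifact_vaf_range: tuple[float, float] = (0.02, 0.09)
    depth_mean: float = 100.0
    depth_dispersion: float = 10.0
    normal_depth_mean: float = 60.0
    vaf_mean: float = 0.4
    vaf_sd: float = 0.1
    vaf_bounds: tuple[float, float] = (0.05, 0.95)
    sample_prefix: str = "S"
    cn_plans: Mapping[str, Sequence[ChromPlan]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.artifact_rate < 1.0:
            raise ValueError("artifact_rate must be in [0, 1)")
        lo, hi = self.artifact_vaf_range
        if not (0.0 < lo <= hi < 0.2):
            raise ValueError("artifact VAF distribution must be bounded below 0.2")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")

    def sample_ids(self) -> list[str]:
        return [f"{self.sample_prefix}{i + 1:02d}" for i in range(self.n_samples)]

    def mutation_count(self, sample_id: str) -> int:
        if isinstance(self.mutations_per_sample, Mapping):
            return int(self.mutations_per_sample[sample_id])
        return int(self.mutations_per_sample)


def generate_reference(config: SimulationConfig):
    """Random reference with exome and transcript annotation.

    Returns ``(genome, exome_intervals, transcripts)``: genome as a dict of
    upper-case sequences, exome intervals as 0-based half-open
    ``(chrom, start, end)`` tuples, transcripts as strand-alternating
    :class:`TranscriptAnnotation` spans over consecutive exons.
    """
    if not config.contig_lengths:
        raise ValueError("empty contig plan")
    for chrom, length in config.contig_lengths.items():
        if length < 1_000:
            raise ValueError(f"contig {chrom} shorter than 1 kb")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    genome: dict[str, str] = {}
    exome: list[tuple[str, int, int]] = []
    transcripts: list[TranscriptAnnotation] = []
    bases = np.array(list("ACGT"))
    period = config.exon_length + config.exon_spacing
    if config.exon_length < 3 or config.exon_spacing < 0:
        raise ValueError("impossible exon plan")
    for chrom in sorted(config.contig_lengths):
        length = config.contig_lengths[chrom]
        genome[chrom] = "".join(bases[rng.choice(4, size=length, p=probs)])
        starts = list(range(config.exon_spacing // 2, length - config.exon_length, period))
        if not starts:
            raise ValueError(f"contig {chrom} too short for the exon plan")
        chrom_exons = [(chrom, s, s + config.exon_length) for s in starts]
        exome.extend(chrom_exons)
        k = max(1, config.exons_per_transcript)
        for t_idx in range(0, len(chrom_exons), k):
            block = chrom_exons[t_idx : t_idx + k]
            strand = "+" if (t_idx // k) % 2 == 0 else "-"
            transcripts.append(
                TranscriptAnnotation(
                    chrom=chrom,
                    start=block[0][1],
                    end=block[-1][2],
                    strand=strand,
                    transcript_id=f"{chrom}.t{t_idx // k + 1}",
                )
            )
    return genome, exome, transcripts


def _context_index(genome: Mapping[str, str], intervals) -> dict[str, list[tuple[str, int]]]:
    """Positions (chrom, 1-based pos) of each pyrimidine-centric trinucleotide."""
    index: dict[str, list[tuple[str, int]]] = {t: [] for t in TRINUCLEOTIDES_32}
    for chrom, start, end in merge_intervals(intervals):
        seq = genome[chrom]
        for p in range(max(start, 1), min(end, len(seq) - 1)):
            tri = seq[p - 1 : p + 2]
            if "N" in tri:
                continue
            canon = revcomp(tri) if tri[1] in "AG" else tri
            index[canon].append((chrom, p + 1))
    return index


def _truncnorm(rng: np.random.Generator, mean, sd, lo, hi, size) -> np.ndarray:
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    # resample rejected draws; falls back to clipping after a few rounds
    for _ in range(20):
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return np.clip(out, lo, hi)


def _nb_depth(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return np.maximum(rng.negative_binomial(dispersion, p, size=size), 1)


def simulate_variants(
    config: SimulationConfig,
    genome: Mapping[str, str],
    exome_intervals,
) -> tuple[list[SomaticVariant], pd.DataFrame]:
    """Simulate signature-driven somatic SNVs with read-sampling noise.

    Each mutation first draws its generating signature from the sample's
    exposure fractions (so exposures are exactly per-signature mutation
    counts), then its channel in proportion to that signature's channel
    probability times the available context opportunity, then a position
    uniformly among territory positions carrying the channel's context.
    Tumor alt counts are Binomial(depth, VAF) at negative-binomial depth and
    truncated-normal clonal VAF.

    Returns ``(variants, truth)`` where truth records the generating
    signature, drawn channel, true VAF and artifact status per variant.
    """
    signatures = config.signatures
    if signatures is None:
        signatures = SignatureMatrix(
            data=pd.DataFrame(
                {"clock": clock_like_signature(), "flat": flat_like_signature()}
            ),
            scheme="SBS96",
        )
    samples = config.sample_ids()
    if config.exposures is not None:
        exposures = config.exposures
        if list(exposures.columns) != signatures.names or list(exposures.index) != samples:
            exposures = exposures.reindex(index=samples, columns=signatures.names)
            if exposures.isna().any().any():
                raise ValueError("exposures must cover every sample and signature")
    else:
        exposures = pd.DataFrame(
            1.0 / signatures.n_signatures, index=samples, columns=signatures.names
        )

    index = _context_index(genome, exome_intervals)
    opportunity = np.array(
        [len(index[channel_context(ch)]) for ch in SBS96_CHANNELS], dtype=float
    )
    W = signatures.data.to_numpy(dtype=float)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    variants: list[SomaticVariant] = []
    truth_rows: list[dict] = []
    # per-signature channel weights in genome space; zero-opportunity check
    sig_weights = []
    for k in range(W.shape[1]):
        missing = (W[:, k] > 1e-9) & (opportunity == 0)
        if missing.any():
            bad = [SBS96_CHANNELS[i] for i in np.nonzero(missing)[0][:5]]
            raise ValueError(
                f"signature {signatures.names[k]!r} has truth channels with zero "
                f"genomic opportunity: {bad}"
            )
        w = W[:, k] * opportunity
        if w.sum() <= 0:
            raise ValueError("no channel has positive probability and opportunity")
        sig_weights.append(w / w.sum())

    for sample in samples:
        n = config.mutation_count(sample)
        if n == 0:
            continue
        e = exposures.loc[sample].to_numpy(dtype=float)
        if (e < 0).any() or e.sum() <= 0:
            raise ValueError(f"invalid exposure fractions for sample {sample}")
        sig_counts = rng.multinomial(n, e / e.sum())
        depths = _nb_depth(rng, config.depth_mean, config.depth_dispersion, n)
        n_depths = _nb_depth(rng, config.normal_depth_mean, config.depth_dispersion, n)
        vafs = _truncnorm(
            rng, config.vaf_mean, config.vaf_sd, *config.vaf_bounds, size=n
        )
        i = 0
        draws: list[tuple[str, int]] = []  # (signature name, channel index)
        for k, n_k in enumerate(sig_counts):
            if n_k == 0:
                continue
            ch_counts = rng.multinomial(n_k, sig_weights[k])
            for ch_idx, count in enumerate(ch_counts):
                draws.extend([(signatures.names[k], ch_idx)] * count)
        for sig_name, ch_idx in draws:
            channel = SBS96_CHANNELS[ch_idx]
            positions = index[channel_context(channel)]
            chrom, pos = positions[int(rng.integers(0, len(positions)))]
            center = genome[chrom][pos - 1]
            ch_ref, ch_alt = channel[2], channel[4]
            if center == ch_ref:  # pyrimidine on the forward strand
                ref, alt = ch_ref, ch_alt
            else:
                ref, alt = center, ch_alt.translate(_COMP)
            depth = int(depths[i])
            t_alt = max(int(rng.binomial(depth, vafs[i])), 1)
            variants.append(
                SomaticVariant(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    variant_class="SNV",
                    tumor_depth=depth,
                    tumor_alt=t_alt,
                    normal_depth=int(n_depths[i]),
                    normal_alt=0,
                    sample_id=sample,
                )
            )
            truth_rows.append(
                {
                    "sample_id": sample,
                    "chrom": chrom,
                    "pos": pos,
                    "signature": sig_name,
                    "channel": channel,
                    "true_vaf": float(vafs[i]),
                    "is_artifact": False,
                }
            )
            i += 1
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "chrom", "pos", "signature", "channel", "true_vaf", "is_artifact"],
    )
    return variants, truth


def inject_artifacts(
    variants: Sequence[SomaticVariant],
    truth: pd.DataFrame,
    config: SimulationConfig,
    genome: Mapping[str, str],
    exome_intervals,
) -> tuple[list[SomaticVariant], pd.DataFrame]:
    """Add low-VAF C>T / G>A deamination-like artifacts to a variant table.

    The number of injected records makes artifacts approximately
    ``config.artifact_rate`` of the augmented table; drawn VAFs are uniform
    over ``config.artifact_vaf_range`` (bounded below 0.2 by construction).
    Injected records are flagged ``is_artifact`` in the returned truth table.
    """
    if config.artifact_rate == 0.0:
        return list(variants), truth.copy()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    index = _context_index(genome, exome_intervals)
    ct_positions = [
        (chrom, pos)
        for context in TRINUCLEOTIDES_32
        if context[1] == "C"
        for (chrom, pos) in index[context]
    ]
    if not ct_positions:
        raise ValueError("territory has no C/G sites for artifact injection")
    per_sample: dict[str, int] = {}
    for v in variants:
        per_sample[v.sample_id] = per_sample.get(v.sample_id, 0) + 1
    rate = config.artifact_rate
    lo, hi = config.artifact_vaf_range
    out = list(variants)
    rows: list[dict] = []
    for sample, n_true in sorted(per_sample.items()):
        n_art = int(round(n_true * rate / (1.0 - rate)))
        picks = rng.integers(0, len(ct_positions), size=n_art)
        vafs = rng.uniform(lo, hi, size=n_art)
        depths = _nb_depth(rng, config.depth_mean, config.depth_dispersion, n_art)
        n_depths = _nb_depth(rng, config.normal_depth_mean, config.depth_dispersion, n_art)
        for j in range(n_art):
            chrom, pos = ct_positions[picks[j]]
            center = genome[chrom][pos - 1]
            ref, alt = ("C", "T") if center == "C" else ("G", "A")
            depth = int(depths[j])
            t_alt = max(int(rng.binomial(depth, vafs[j])), 1)
            out.append(
                SomaticVariant(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    variant_class="SNV",
                    tumor_depth=depth,
                    tumor_alt=t_alt,
                    normal_depth=int(n_depths[j]),
                    normal_alt=0,
                    sample_id=sample,
                )
            )
            rows.append(
                {
                    "sample_id": sample,
                    "chrom": chrom,
                    "pos": pos,
                    "signature": None,
                    "channel": None,
                    "true_vaf": float(vafs[j]),
                    "is_artifact": True,
                }
            )
    truth_out = pd.concat([truth, pd.DataFrame(rows, columns=truth.columns)], ignore_index=True)
    return out, truth_out


def _baf_for_cn(cn: int) -> float:
    if cn <= 1:
        return 0.0
    minor = cn // 2
    return minor / cn


def simulate_cn_profiles(config: SimulationConfig) -> dict[str, list[CnSegment]]:
    """Per-sample CN segment tables following ``config.cn_plans``.

    A plan with ``n_switches == 0`` yields one flat segment at the baseline
    CN; otherwise the chromosome is cut into ``n_switches + 1`` segments
    oscillating among the plan's CN states (adjacent segments always differ),
    so the realized switch count is exactly as configured.  BAF values follow
    the balanced allelic split of each integer CN.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
    profiles: dict[str, list[CnSegment]] = {}
    for sample, plans in config.cn_plans.items():
        segments: list[CnSegment] = []
        for plan in plans:
            n_seg = plan.n_switches + 1
            if n_seg * plan.min_segment_bp > plan.length_bp:
                raise ValueError(
                    f"{plan.chrom}: {plan.n_switches} switches do not fit in "
                    f"{plan.length_bp} bp at min segment {plan.min_segment_bp} bp"
                )
            if plan.n_switches == 0:
                segments.append(
                    CnSegment(
                        chrom=plan.chrom,
                        start=1,
                        end=plan.length_bp,
                        total_cn=plan.baseline_cn,
                        baf=_baf_for_cn(plan.baseline_cn),
                        sample_id=sample,
                    )
                )
                continue
            if len(plan.states) < 2:
                raise ValueError("oscillation requires at least 2 CN states")
            free = plan.length_bp - n_seg * plan.min_segment_bp
            extras = rng.multinomial(free, np.full(n_seg, 1.0 / n_seg)) if free > 0 else np.zeros(n_seg, dtype=int)
            lengths = plan.min_segment_bp + extras
            states = list(plan.states)
            cn_seq = [states[0]]
            for _ in range(plan.n_switches):
                choices = [s for s in states if s != cn_seq[-1]]
                cn_seq.append(choices[int(rng.integers(0, len(choices)))])
            start = 1
            for seg_len, cn in zip(lengths, cn_seq):
                segments.append(
                    CnSegment(
                        chrom=plan.chrom,
                        start=start,
                        end=start + int(seg_len) - 1,
                        total_cn=int(cn),
                        baf=_baf_for_cn(int(cn)),
                        sample_id=sample,
                    )
                )
                start += int(seg_len)
        profiles[sample] = segments
    return profiles


def make_preset(name: str, seed: int = 0) -> SimulationConfig:
    """Named cohort presets for the cross-species cohort archetypes.

    ``bovine-like``: a small cohort with a very high mutation rate dominated
    by the alkylation-type (PT-like) signature at 49-89% exposure plus a
    background signature.  ``canine-like``: a larger low-rate cohort of
    clock-plus-background mutations, one mismatch-repair hypermutator with a
    13x mutation load, and injected deamination artifacts.
    ``pt-timecourse``: samples with linearly increasing mutation counts whose
    increment is PT-like.
    """
    refdb = synthetic_reference_db()
    if name == "bovine-like":
        n = 8
        sigs = SignatureMatrix(
            data=pd.DataFrame(
                {"BF-A": pt_like_signature(), "BF-B": clock_like_signature()}
            ),
            scheme="SBS96",
        )
        samples = [f"BT{i + 1:02d}" for i in range(n)]
        bfa = np.linspace(0.49, 0.89, n)
        exposures = pd.DataFrame(
            {"BF-A": bfa, "BF-B": 1 - bfa}, index=samples
        )
        return SimulationConfig(
            seed=seed,
            n_samples=n,
            sample_prefix="BT",
            mutations_per_sample=5_000,
            signatures=sigs,
            exposures=exposures,
        )
    if name == "canine-like":
        n = 12
        samples = [f"DD{i + 1:02d}" for i in range(n)]
        sigs = SignatureMatrix(
            data=pd.DataFrame(
                {
                    "SBS1": refdb.data["SBS1"],
                    "SBS5": refdb.data["SBS5"],
                    "SBS6": refdb.data["SBS6"],
                    "SBS44": refdb.data["SBS44"],
                }
            ),
            scheme="SBS96",
        )
        exposures = pd.DataFrame(
            {"SBS1": 0.4, "SBS5": 0.6, "SBS6": 0.0, "SBS44": 0.0}, index=samples
        )
        counts = {s: 150 for s in samples}
        # one mismatch-repair hypermutator at ~13x the cohort rate
        hyper = samples[-1]
        counts[hyper] = 1_950
        exposures.loc[hyper] = {"SBS1": 0.15, "SBS5": 0.15, "SBS6": 0.45, "SBS44": 0.25}
        return SimulationConfig(
            seed=seed,
            n_samples=n,
            sample_prefix="DD",
            mutations_per_sample=counts,
            signatures=sigs,
            exposures=exposures,
            artifact_rate=0.1,
        )
    if name == "pt-timecourse":
        n = 8
        samples = [f"PT{i + 1:02d}" for i in range(n)]
        sigs = SignatureMatrix(
            data=pd.DataFrame(
                {"PT-A": pt_like_signature(), "PT-B": clock_like_signature()}
            ),
            scheme="SBS96",
        )
        frac = np.linspace(0.3, 0.8, n)
        exposures = pd.DataFrame({"PT-A": frac, "PT-B": 1 - frac}, index=samples)
        counts = {s: 500 + 500 * i for i, s in enumerate(samples)}
        return SimulationConfig(
            seed=seed,
            n_samples=n,
            sample_prefix="PT",
            mutations_per_sample=counts,
            signatures=sigs,
            exposures=exposures,
        )
    raise ValueError(f"unknown preset {name!r}")
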