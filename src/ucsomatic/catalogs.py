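"""Mutational catalogs over the standard SBS96 / DBS78 / ID83 channel schemes.

Single-base substitutions are classified by the six pyrimidine-centric
substitution types in their trinucleotide context (96 channels); doublet
substitutions by the 78-channel scheme with reverse-complement
canonicalization of the reference doublet; and small indels by the 83-channel
scheme encoding indel length, deleted/inserted base (for 1-bp events),
tandem-repeat copy number, and microhomology length for non-repeat deletions.

Mutational opportunities — the trinucleotide composition of a genomic
territory such as "exons plus 2 bp flanking each exon" — let catalogs
counted in one territory be converted into the context space of another
(e.g. an exome catalog expressed relative to the whole human genome) so that
signatures extracted from different species are comparable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ucsomatic.filtering import SomaticVariant

__all__ = [
    "SBS96_CHANNELS",
    "DBS78_CHANNELS",
    "ID83_CHANNELS",
    "TRINUCLEOTIDES_32",
    "MutationCatalog",
    "OpportunityVector",
    "sbs_channel",
    "dbs_channel",
    "id_channel",
    "classify_indel",
    "build_catalog",
    "compute_opportunities",
    "convert_catalog",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_PYRIMIDINE_BASE = {"A": "T", "G": "C", "C": "C", "T": "T"}
_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _sbs96_order() -> list[str]:
    return [
        f"{five}[{sub}]{three}"
        for sub in _SUBSTITUTIONS
        for five in "ACGT"
        for three in "ACGT"
    ]


#: fixed channel order: substitutions C>A..T>G, flanks lexicographic
SBS96_CHANNELS: tuple[str, ...] = tuple(_sbs96_order())

#: pyrimidine-centric trinucleotides, same nesting as the SBS channel order
TRINUCLEOTIDES_32: tuple[str, ...] = tuple(
    f"{five}{center}{three}" for center in "CT" for five in "ACGT" for three in "ACGT"
)

# Canonical reference doublets; palindromic ones (AT, CG, GC, TA) collapse
# reverse-complement-equivalent alternates onto the conventional representative.
_DBS_CANONICAL_REFS = ("AC", "AT", "CC", "CG", "CT", "GC", "TA", "TC", "TG", "TT")
_DBS_PALINDROME_ALT = {
    "AT": {"TG": "CA", "GG": "CC", "TC": "GA"},
    "CG": {"AC": "GT", "GA": "TC", "AA": "TT"},
    "GC": {"TT": "AA", "CT": "AG", "TG": "CA"},
    "TA": {"AG": "CT", "CC": "GG", "AC": "GT"},
}


def _dbs78_order() -> list[str]:
    channels = []
    for ref in _DBS_CANONICAL_REFS:
        alts = set()
        for a0, a1 in itertools.product("ACGT", repeat=2):
            alt = a0 + a1
            if a0 == ref[0] or a1 == ref[1]:
                continue
            alt = _DBS_PALINDROME_ALT.get(ref, {}).get(alt, alt)
            alts.add(alt)
        channels.extend(f"{ref}>{alt}" for alt in sorted(alts))
    return channels


DBS78_CHANNELS: tuple[str, ...] = tuple(_dbs78_order())


def _id83_order() -> list[str]:
    channels = []
    for base in "CT":
        channels += [f"1:Del:{base}:{n}" for n in range(6)]
    for base in "CT":
        channels += [f"1:Ins:{base}:{n}" for n in range(6)]
    for length in (2, 3, 4, 5):
        channels += [f"{length}:Del:R:{n}" for n in range(6)]
    for length in (2, 3, 4, 5):
        channels += [f"{length}:Ins:R:{n}" for n in range(6)]
    for length in (2, 3, 4, 5):
        max_mh = 5 if length == 5 else length - 1  # the 5+ class covers >= 6 bp deletions
        channels += [f"{length}:Del:M:{n}" for n in range(1, max_mh + 1)]
    return channels


ID83_CHANNELS: tuple[str, ...] = tuple(_id83_order())
assert len(SBS96_CHANNELS) == 96 and len(DBS78_CHANNELS) == 78 and len(ID83_CHANNELS) == 83

_SCHEME_CHANNELS = {
    "SBS96": SBS96_CHANNELS,
    "DBS78": DBS78_CHANNELS,
    "ID83": ID83_CHANNELS,
}


def channel_context(channel: str) -> str:
    """Trinucleotide context of an SBS96 channel label, e.g. A[C>T]G -> ACG."""
    return channel[0] + channel[2] + channel[6]


def _check_base(b: str, what: str) -> str:
    b = b.upper()
    if b not in "ACGT":
        raise ValueError(f"{what} must be one of A/C/G/T, got {b!r}")
    return b


def sbs_channel(ref: str, alt: str, five_prime: str, three_prime: str) -> str:
    """SBS96 channel of a single-base substitution in its trinucleotide context.

    Purine-reference substitutions are reverse-complemented to the
    pyrimidine representation: the substitution is complemented and the 5'/3'
    flanks are swapped and complemented.
    """
    ref = _check_base(ref, "ref")
    alt = _check_base(alt, "alt")
    five_prime = _check_base(five_prime, "five_prime")
    three_prime = _check_base(three_prime, "three_prime")
    if ref == alt:
        raise ValueError(f"ref and alt are identical ({ref})")
    if ref in "AG":
        ref, alt = revcomp(ref), revcomp(alt)
        five_prime, three_prime = revcomp(three_prime), revcomp(five_prime)
    return f"{five_prime}[{ref}>{alt}]{three_prime}"


def dbs_channel(ref_doublet: str, alt_doublet: str) -> str:
    """DBS78 channel of a doublet substitution (both positions must change)."""
    ref = ref_doublet.upper()
    alt = alt_doublet.upper()
    for d, what in ((ref, "ref_doublet"), (alt, "alt_doublet")):
        if len(d) != 2 or any(b not in "ACGT" for b in d):
            raise ValueError(f"{what} must be a 2-mer over A/C/G/T, got {d!r}")
    if ref == alt:
        raise ValueError(f"ref and alt doublets are identical ({ref})")
    if ref[0] == alt[0] or ref[1] == alt[1]:
        raise ValueError(
            f"{ref}>{alt} is not a true doublet substitution (both bases must change)"
        )
    if ref not in _DBS_CANONICAL_REFS:
        ref, alt = revcomp(ref), revcomp(alt)
    alt = _DBS_PALINDROME_ALT.get(ref, {}).get(alt, alt)
    return f"{ref}>{alt}"


def _run_length(flank: str, unit: str, reverse: bool = False) -> int:
    """Number of consecutive copies of ``unit`` at the start (or end) of ``flank``."""
    L = len(unit)
    n = 0
    if reverse:
        while len(flank) >= (n + 1) * L and flank[len(flank) - (n + 1) * L : len(flank) - n * L] == unit:
            n += 1
    else:
        while len(flank) >= (n + 1) * L and flank[n * L : (n + 1) * L] == unit:
            n += 1
    return n


def classify_indel(kind: str, seq: str, left_flank: str, right_flank: str) -> str:
    """ID83 channel of a left-aligned indel given its flanking sequence.

    ``kind`` is ``"Del"`` or ``"Ins"``; ``seq`` is the deleted or inserted
    sequence; flanks are reference sequence immediately 5' and 3' of the
    event, each at least 5x the indel length (and >= 5 bp).

    1-bp events are labelled by base (pyrimidine representation) and
    homopolymer length; longer events by tandem-repeat copy number, or for
    deletions without a tandem copy, by flanking microhomology length.
    """
    if kind not in ("Del", "Ins"):
        raise ValueError(f"kind must be 'Del' or 'Ins', got {kind!r}")
    seq = seq.upper()
    if not seq or any(b not in "ACGT" for b in seq):
        raise ValueError(f"invalid indel sequence {seq!r}")
    L = len(seq)
    need = max(5 * L, 5)
    if len(left_flank) < need or len(right_flank) < need:
        raise ValueError(
            f"insufficient flanking sequence for a {L}-bp {kind} "
            f"(need {need} bp each side)"
        )
    left_flank = left_flank.upper()
    right_flank = right_flank.upper()

    # tandem copies of the indel unit adjacent to the event
    copies = _run_length(right_flank, seq) + _run_length(left_flank, seq, reverse=True)
    if kind == "Del":
        copies += 1  # the deleted copy itself is part of the reference run

    if L == 1:
        base = _PYRIMIDINE_BASE[seq]
        n = min(copies - 1, 5) if kind == "Del" else min(copies, 5)
        return f"1:{kind}:{base}:{n}"

    size = min(L, 5)
    if kind == "Del" and copies == 1:
        # no tandem repeat: check flanking microhomology in both directions
        mh_right = 0
        while mh_right < L - 1 and right_flank[mh_right] == seq[mh_right]:
            mh_right += 1
        mh_left = 0
        while mh_left < L - 1 and left_flank[-1 - mh_left] == seq[-1 - mh_left]:
            mh_left += 1
        mh = min(max(mh_right, mh_left), L - 1, 5)
        if mh >= 1:
            return f"{size}:Del:M:{mh}"
    n = min(copies - 1, 5) if kind == "Del" else min(copies, 5)
    return f"{size}:{kind}:R:{n}"


def _indel_event(v: SomaticVariant) -> tuple[str, str, int]:
    """Normalize a VCF-style anchored indel to (kind, sequence, 1-based event start)."""
    ref, alt = v.ref.upper(), v.alt.upper()
    if v.variant_class == "DEL":
        if len(ref) > len(alt) and ref.startswith(alt):
            return "Del", ref[len(alt) :], v.pos + len(alt)
        if alt in ("", "-"):
            return "Del", ref, v.pos
    elif v.variant_class == "INS":
        if len(alt) > len(ref) and alt.startswith(ref):
            return "Ins", alt[len(ref) :], v.pos + len(ref)
        if ref in ("", "-"):
            return "Ins", alt, v.pos
    raise ValueError(
        f"cannot interpret {v.variant_class} with ref={v.ref!r} alt={v.alt!r} "
        f"at {v.chrom}:{v.pos} (expected VCF-anchored alleles)"
    )


def id_channel(variant: SomaticVariant, genome, flank: int = 30) -> str:
    """ID83 channel of an indel variant, retrieving flanks from ``genome``."""
    kind, seq, start = _indel_event(variant)
    L = len(seq)
    need = max(max(5 * L, 5), flank)
    left_start = max(0, start - 1 - need)
    left = str(genome[variant.chrom][left_start : start - 1]).upper()
    if kind == "Del":
        right = str(genome[variant.chrom][start - 1 + L : start - 1 + L + need]).upper()
    else:
        right = str(genome[variant.chrom][start - 1 : start - 1 + need]).upper()
    return classify_indel(kind, seq, left, right)


@dataclass
class MutationCatalog:
    """Per-sample mutation counts over a fixed channel scheme.

    ``counts`` is a DataFrame with channels as rows (in the published fixed
    order) and samples as columns; column sums equal the number of variants
    admitted to the scheme for that sample.
    """

    counts: pd.DataFrame
    scheme: str
    skipped: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        channels = _SCHEME_CHANNELS.get(self.scheme)
        if channels is None:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        self.counts = self.counts.reindex(list(channels)).fillna(0.0)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("catalog counts must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def channels(self) -> list[str]:
        return list(self.counts.index)

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def spectrum(self, sample_id: str) -> np.ndarray:
        return self.counts[sample_id].to_numpy(dtype=float)

    def pooled(self) -> np.ndarray:
        """Cohort-pooled spectrum (sum over samples)."""
        return self.counts.sum(axis=1).to_numpy(dtype=float)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="channel")

    @classmethod
    def from_tsv(cls, path, scheme: str) -> "MutationCatalog":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(counts=df, scheme=scheme)


def build_catalog(variants, genome, scheme: str, sample_ids=None) -> MutationCatalog:
    """Count variants into a :class:`MutationCatalog` for one channel scheme.

    Variants outside the scheme (indels under SBS96, SNVs under ID83, MNVs of
    length > 2 anywhere, or N-containing contexts) are skipped and tallied in
    ``catalog.skipped``.  Loci whose context cannot be retrieved from the
    reference raise ``KeyError`` listing the offending positions.
    """
    if scheme not in _SCHEME_CHANNELS:
        raise ValueError(f"unknown scheme {scheme!r}")
    variants = list(variants)
    samples = list(sample_ids) if sample_ids is not None else sorted(
        {v.sample_id for v in variants}
    )
    channels = _SCHEME_CHANNELS[scheme]
    counts = pd.DataFrame(0, index=list(channels), columns=samples, dtype=float)
    skipped: dict[str, int] = {}
    bad_loci: list[str] = []

    for v in variants:
        if v.sample_id not in counts.columns:
            counts[v.sample_id] = 0.0
        try:
            label = _classify_for_scheme(v, genome, scheme)
        except (KeyError, IndexError):
            bad_loci.append(f"{v.chrom}:{v.pos}")
            continue
        except _Skip as s:
            skipped[s.reason] = skipped.get(s.reason, 0) + 1
            continue
        counts.loc[label, v.sample_id] += 1

    if bad_loci:
        raise KeyError(f"loci outside the reference genome: {', '.join(bad_loci[:20])}")
    return MutationCatalog(counts=counts, scheme=scheme, skipped=skipped)


class _Skip(Exception):
    def __init__(self, reason: str):
        self.reason = reason


def _classify_for_scheme(v: SomaticVariant, genome, scheme: str) -> str:
    if scheme == "SBS96":
        if v.variant_class != "SNV":
            raise _Skip(f"non-SNV ({v.variant_class})")
        tri = str(genome[v.chrom][v.pos - 2 : v.pos + 1]).upper()
        if len(tri) != 3:
            raise KeyError("context beyond contig bounds")
        if "N" in tri or "N" in (v.ref + v.alt):
            raise _Skip("N context")
        if tri[1] != v.ref.upper():
            raise ValueError(
                f"reference mismatch at {v.chrom}:{v.pos}: genome has {tri[1]}, "
                f"variant ref is {v.ref}"
            )
        return sbs_channel(v.ref, v.alt, tri[0], tri[2])
    if scheme == "DBS78":
        if v.variant_class != "MNV" or len(v.ref) != 2 or len(v.alt) != 2:
            raise _Skip(f"non-doublet ({v.variant_class})")
        if "N" in (v.ref + v.alt).upper():
            raise _Skip("N context")
        try:
            return dbs_channel(v.ref, v.alt)
        except ValueError:
            raise _Skip("non-canonical doublet")
    # ID83
    if v.variant_class not in ("INS", "DEL"):
        raise _Skip(f"non-indel ({v.variant_class})")
    return id_channel(v, genome)


@dataclass
class OpportunityVector:
    """Counts of the 32 pyrimidine-centric trinucleotides over a territory."""

    counts: pd.Series
    territory_bp: int = 0

    def __post_init__(self) -> None:
        self.counts = self.counts.reindex(list(TRINUCLEOTIDES_32)).fillna(0.0)

    def frequencies(self) -> pd.Series:
        total = float(self.counts.sum())
        if total <= 0:
            raise ValueError("degenerate territory: no counted trinucleotides")
        return self.counts / total

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", header=["count"], index_label="context")

    @classmethod
    def from_tsv(cls, path) -> "OpportunityVector":
        s = pd.read_csv(path, sep="\t", index_col=0).iloc[:, 0]
        return cls(counts=s)


def merge_intervals(intervals, flank: int = 0):
    """Merge (chrom, start, end) 0-based half-open intervals after extending by ``flank``."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        if end <= start:
            raise ValueError(f"empty interval {chrom}:{start}-{end}")
        by_chrom.setdefault(chrom, []).append((max(0, start - flank), end + flank))
    merged = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((chrom, cur_s, cur_e))
    return merged


def compute_opportunities(genome, intervals, flank: int = 2) -> OpportunityVector:
    """Trinucleotide opportunity counts over a flank-extended, merged territory.

    Every position of the merged territory whose full trinucleotide lies
    within the contig and contains no N contributes one count to its
    pyrimidine-centric context.  The default 2-bp flank mirrors the
    "exons plus 2 bp flanking each exon" splice-site territory.
    """
    intervals = list(intervals)
    if not intervals:
        raise ValueError("empty interval list")
    if flank < 0:
        raise ValueError("flank must be >= 0")
    counts = {t: 0 for t in TRINUCLEOTIDES_32}
    territory = 0
    for chrom, start, end in merge_intervals(intervals, flank=flank):
        seq = str(genome[chrom][max(0, start - 1) : end + 1]).upper()
        # offset of `start` within the fetched slice
        off = start - max(0, start - 1)
        territory += end - start
        for i in range(end - start):
            j = off + i
            if j == 0:  # contig start: no 5' base
                continue
            tri = seq[j - 1 : j + 2]
            if len(tri) != 3 or "N" in tri:
                continue
            if tri[1] in "AG":
                tri = revcomp(tri)
            counts[tri] += 1
    return OpportunityVector(counts=pd.Series(counts, dtype=float), territory_bp=territory)


def convert_catalog(
    catalog: MutationCatalog,
    source_opps: OpportunityVector,
    target_opps: OpportunityVector,
    preserve_totals: bool = True,
) -> MutationCatalog:
    """Re-express an SBS96 catalog relative to another territory's opportunities.

    Each channel count is reweighted by the ratio of target to source relative
    trinucleotide frequency of its context; with ``preserve_totals`` each
    sample is then rescaled so its total mutation count is unchanged.
    """
    if catalog.scheme != "SBS96":
        raise ValueError("opportunity conversion is defined for SBS96 catalogs")
    src = source_opps.frequencies()
    tgt = target_opps.frequencies()
    if (src <= 0).any():
        zero = list(src.index[src <= 0])
        raise ValueError(f"zero opportunity in source territory for context(s): {zero}")
    weights = np.array(
        [tgt[channel_context(ch)] / src[channel_context(ch)] for ch in catalog.channels]
    )
    converted = catalog.counts.mul(weights, axis=0)
    if preserve_totals:
        old = catalog.counts.sum(axis=0)
        new = converted.sum(axis=0)
        scale = old.divide(new).where(new > 0, 0.0)
        converted = converted.mul(scale, axis=1)
    return MutationCatalog(counts=converted, scheme="SBS96", skipped=dict(catalog.skipped))
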