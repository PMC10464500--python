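"""Transcriptional strand assignment and exact strand-bias testing.

Mutations inside annotated transcripts are assigned to the genic transcribed
(template) or untranscribed (coding) strand using the pyrimidine convention:
a substitution is recorded with its pyrimidine reference base, and the strand
carrying that pyrimidine determines the assignment.  Damage-driven processes
acting on one base (e.g. alkylated adenines repaired preferentially on the
transcribed strand) show up as an excess on one strand, tested per mutation
type with an exact conditional test: under the null of no bias the
transcribed-strand count is Binomial(n, 1/2) given the total n.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import binomtest

from ucsomatic.catalogs import sbs_channel
from ucsomatic.filtering import SomaticVariant

__all__ = [
    "TranscriptAnnotation",
    "assign_strand",
    "strand_counts",
    "exact_strand_test",
]


@dataclass(frozen=True)
class TranscriptAnnotation:
    """A strand-annotated transcript interval (0-based half-open, as in BED)."""

    chrom: str
    start: int
    end: int
    strand: str
    transcript_id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"transcript {self.transcript_id}: start >= end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript {self.transcript_id}: strand must be + or -")

    def covers(self, chrom: str, pos: int) -> bool:
        """Whether the 1-based position ``pos`` lies inside the transcript."""
        return self.chrom == chrom and self.start < pos <= self.end


def assign_strand(
    variant: SomaticVariant, transcripts: Sequence[TranscriptAnnotation]
) -> str:
    """Assign an SNV to 'transcribed', 'untranscribed', or 'unassigned'.

    The mutated pyrimidine on the template strand of the covering gene means
    the lesion was on the transcribed strand; on the coding strand,
    untranscribed.  Intergenic positions and positions covered by transcripts
    on both strands are unassigned.  Overlapping same-strand transcripts
    collapse to a single assignment.
    """
    if variant.variant_class != "SNV":
        return "unassigned"
    strands = {t.strand for t in transcripts if t.covers(variant.chrom, variant.pos)}
    if len(strands) != 1:
        return "unassigned"
    gene_strand = strands.pop()
    pyrimidine_strand = "+" if variant.ref.upper() in "CT" else "-"
    # coding strand == gene strand; template (transcribed) strand is opposite
    return "untranscribed" if pyrimidine_strand == gene_strand else "transcribed"


def strand_counts(
    variants: Iterable[SomaticVariant],
    transcripts: Sequence[TranscriptAnnotation],
    genome=None,
    by: str = "substitution",
) -> pd.DataFrame:
    """Per-mutation-type strand counts with exact bias p-values.

    ``by='substitution'`` groups by the six pyrimidine substitution types;
    ``by='channel'`` groups by full SBS96 channel (requires ``genome`` for
    trinucleotide context).  Returns a DataFrame indexed by mutation type
    with columns transcribed / untranscribed / unassigned / p_value.
    """
    if by not in ("substitution", "channel"):
        raise ValueError("by must be 'substitution' or 'channel'")
    if by == "channel" and genome is None:
        raise ValueError("channel-level counts require a reference genome")
    rows: dict[str, dict[str, int]] = {}
    for v in variants:
        if v.variant_class != "SNV":
            continue
        if by == "channel":
            tri = str(genome[v.chrom][v.pos - 2 : v.pos + 1]).upper()
            if len(tri) != 3 or "N" in tri:
                continue
            key = sbs_channel(v.ref, v.alt, tri[0], tri[2])
        else:
            ref, alt = v.ref.upper(), v.alt.upper()
            if ref in "AG":
                comp = str.maketrans("ACGT", "TGCA")
                ref, alt = ref.translate(comp), alt.translate(comp)
            key = f"{ref}>{alt}"
        group = rows.setdefault(
            key, {"transcribed": 0, "untranscribed": 0, "unassigned": 0}
        )
        group[assign_strand(v, transcripts)] += 1
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    pvals = []
    for _, r in out.iterrows():
        if r["transcribed"] + r["untranscribed"] >= 1:
            pvals.append(exact_strand_test(int(r["transcribed"]), int(r["untranscribed"])))
        else:
            pvals.append(float("nan"))
    out["p_value"] = pvals
    return out


def exact_strand_test(n_transcribed: int, n_untranscribed: int) -> float:
    """Two-sided exact test of strand symmetry for a pair of counts.

    Conditional on the total, the transcribed count is Binomial(n, 1/2)
    under the null; the two-sided p-value sums the probabilities of all
    outcomes no more likely than the observed one (minimum-likelihood
    method).  This is the exact conditional form of comparing two Poisson
    rates.
    """
    if n_transcribed < 0 or n_untranscribed < 0:
        raise ValueError("counts must be non-negative")
    n = n_transcribed + n_untranscribed
    if n == 0:
        raise ValueError("both strand counts are zero")
    return float(binomtest(n_transcribed, n, 0.5).pvalue)
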