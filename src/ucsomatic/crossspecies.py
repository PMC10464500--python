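"""Gene-level recurrence and cross-species comparison through orthologs.

Cohorts from different species cannot be compared gene-by-gene directly;
only genes with a one-to-one orthologous relationship define an unambiguous
mapping.  A gene is called recurrently mutated when it carries a non-silent
mutation in at least a given fraction of the cohort (5% by default), and the
cross-species overlap is the set of one-to-one ortholog pairs recurrent in
both cohorts.  Cohort subgroup enrichment (e.g. mutation frequency in one
breed group versus the rest) is tested with the Pearson chi-squared test on
the 2x2 table, without continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import chi2_contingency

from ucsomatic.filtering import SomaticVariant

__all__ = [
    "OrthologTable",
    "gene_mutation_matrix",
    "recurrent_genes",
    "shared_recurrent_genes",
    "group_association_test",
    "DEFAULT_SILENT_CONSEQUENCES",
]

#: consequence strings not counted as gene-mutating (configurable)
DEFAULT_SILENT_CONSEQUENCES = frozenset(
    {
        "synonymous",
        "silent",
        "intron",
        "intronic",
        "intergenic",
        "5_prime_utr",
        "3_prime_utr",
        "upstream",
        "downstream",
        "non_coding",
    }
)


@dataclass
class OrthologTable:
    """One-to-one ortholog pairs between two species' gene namespaces.

    Built from rows of ``(gene_a, gene_b, relation)``; only rows with
    relation ``"one-to-one"`` are retained, and the retained mapping must be
    a partial bijection (no gene may appear twice on either side).
    """

    pairs: list[tuple[str, str]]

    @classmethod
    def from_rows(cls, rows: Iterable[tuple]) -> "OrthologTable":
        pairs = [(a, b) for a, b, *rest in rows if (rest[0] if rest else "one-to-one") == "one-to-one"]
        return cls(pairs=pairs)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OrthologTable":
        cols = list(df.columns)
        rel = df[cols[2]] if len(cols) > 2 else "one-to-one"
        keep = df[rel == "one-to-one"] if len(cols) > 2 else df
        return cls(pairs=list(zip(keep[cols[0]], keep[cols[1]])))

    def __post_init__(self) -> None:
        a_side = [a for a, _ in self.pairs]
        b_side = [b for _, b in self.pairs]
        for side, name in ((a_side, "A"), (b_side, "B")):
            dup = {g for g in side if side.count(g) > 1}
            if dup:
                raise ValueError(
                    f"duplicated gene(s) on side {name} violate one-to-one orthology: "
                    f"{sorted(dup)[:10]}"
                )

    def a_to_b(self) -> dict[str, str]:
        return dict(self.pairs)

    def b_to_a(self) -> dict[str, str]:
        return {b: a for a, b in self.pairs}

    def reversed(self) -> "OrthologTable":
        return OrthologTable(pairs=[(b, a) for a, b in self.pairs])


def gene_mutation_matrix(
    variants: Iterable[SomaticVariant],
    sample_ids: Sequence[str],
    silent_consequences: Iterable[str] = DEFAULT_SILENT_CONSEQUENCES,
) -> pd.DataFrame:
    """Boolean samples x genes matrix of non-silent mutation status.

    Every sample in ``sample_ids`` appears as a row even if unmutated;
    variants without a gene annotation or with a silent consequence are
    ignored.
    """
    silent = set(silent_consequences)
    mutated: dict[str, set[str]] = {}
    for v in variants:
        if v.gene is None:
            continue
        if v.consequence is not None and v.consequence in silent:
            continue
        mutated.setdefault(v.gene, set()).add(v.sample_id)
    genes = sorted(mutated)
    df = pd.DataFrame(False, index=list(sample_ids), columns=genes)
    for g, samples in mutated.items():
        for s in samples:
            if s in df.index:
                df.loc[s, g] = True
    return df


def recurrent_genes(matrix: pd.DataFrame, min_fraction: float = 0.05) -> set[str]:
    """Genes mutated in at least ``min_fraction`` of samples (inclusive)."""
    n = matrix.shape[0]
    if n < 1:
        raise ValueError("matrix has no samples")
    frac = matrix.sum(axis=0) / n
    if min_fraction <= 0:
        return set(frac.index[frac > 0])
    return set(frac.index[frac >= min_fraction])


def shared_recurrent_genes(
    matrix_a: pd.DataFrame,
    matrix_b: pd.DataFrame,
    orthologs: OrthologTable,
    min_fraction: float = 0.05,
) -> set[tuple[str, str]]:
    """One-to-one ortholog pairs recurrently mutated in both cohorts."""
    rec_a = recurrent_genes(matrix_a, min_fraction)
    rec_b = recurrent_genes(matrix_b, min_fraction)
    return {(a, b) for a, b in orthologs.pairs if a in rec_a and b in rec_b}


def group_association_test(
    mutated_a: int, total_a: int, mutated_b: int, total_b: int
) -> tuple[float, float]:
    """Pearson chi-squared test (1 df, no continuity correction) on a 2x2 table.

    Compares the mutated fraction between two sample groups; returns
    ``(statistic, p_value)``.  Raises on degenerate tables (a zero margin).
    """
    for m, t, name in ((mutated_a, total_a, "A"), (mutated_b, total_b, "B")):
        if t <= 0:
            raise ValueError(f"group {name} has no samples")
        if not 0 <= m <= t:
            raise ValueError(f"group {name}: mutated count {m} outside [0, {t}]")
    table = [
        [mutated_a, total_a - mutated_a],
        [mutated_b, total_b - mutated_b],
    ]
    col_sums = [table[0][0] + table[1][0], table[0][1] + table[1][1]]
    if 0 in col_sums:
        raise ValueError("degenerate 2x2 table: a zero margin")
    res = chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)
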