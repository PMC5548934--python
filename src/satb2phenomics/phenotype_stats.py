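"""Phenotype-term tabulation and missense-vs-LoF group comparison.

Individuals are coded with binary HPO-style terms; each carries a mutation
class label (``lof`` or ``missense``).  Missing entries are coded explicitly
(NA) and excluded from denominators, matching the varying denominators of
clinical cohort reporting.  The packaged study fixture transcribes the
recurrent clinical features of the 19-individual SATB2 cohort
(e.g. cleft palate 9/19, absent/near-absent speech 16/19).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

CLASS_LABELS = ("lof", "missense")


@dataclass
class PhenotypeMatrix:
    """Individuals x binary terms, with a per-individual mutation class."""

    values: pd.DataFrame  # index individual_id, columns terms; 1/0/NaN
    mutation_class: pd.Series  # index individual_id

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate individual ids")
        if not self.values.index.equals(self.mutation_class.index):
            raise ValueError("mutation_class index must match individuals")
        bad = set(self.mutation_class.dropna()) - set(CLASS_LABELS)
        if bad:
            raise ValueError(f"unknown mutation classes: {sorted(bad)}")
        self.values = self.values.astype(float)

    @property
    def terms(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_individuals(self) -> int:
        return len(self.values)


@dataclass
class GroupComparison:
    table: pd.DataFrame  # per-term 2x2 cells, p, q
    skipped: list[str]
    alpha: float
    no_significant_differences: bool


def load_study_phenotypes() -> PhenotypeMatrix:
    """The transcribed 19-individual phenotype fixture (11 LoF, 8 missense)."""
    with resources.files("satb2phenomics.data").joinpath(
            "phenotypes_satb2.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", na_values=["NA"])
    df = df.set_index("individual_id")
    return PhenotypeMatrix(df.drop(columns=["mutation_class"]),
                           df["mutation_class"])


def phenotype_matrix_from_frame(df: pd.DataFrame) -> PhenotypeMatrix:
    df = df.set_index("individual_id")
    return PhenotypeMatrix(df.drop(columns=["mutation_class"]),
                           df["mutation_class"])


def recurrent_terms(m: PhenotypeMatrix) -> pd.Series:
    """Counts of terms used more than once (count >= 2), sorted by count
    descending then term label — the heat-map tabulation rule."""
    if m.values.empty:
        raise ValueError("empty phenotype matrix")
    counts = m.values.sum(axis=0, skipna=True).astype(int)
    counts = counts[counts >= 2]
    order = sorted(counts.index, key=lambda t: (-counts[t], t))
    return counts.loc[order]


def feature_fractions(m: PhenotypeMatrix) -> pd.DataFrame:
    """Per-term k/n with missing entries excluded from n.

    Returns columns ``k``, ``n``, ``fraction_text`` (the "9/19" style string)
    and ``fraction`` (decimal; NaN when n = 0).
    """
    rows = []
    for term in m.terms:
        col = m.values[term]
        n = int(col.notna().sum())
        k = int(col.sum(skipna=True))
        rows.append({
            "term": term, "k": k, "n": n,
            "fraction_text": f"{k}/{n}" if n else "undefined",
            "fraction": k / n if n else np.nan,
        })
    return pd.DataFrame(rows).set_index("term")


def compare_groups(m: PhenotypeMatrix, alpha: float = 0.05) -> GroupComparison:
    """Two-sided exact test per term on the lof-vs-missense 2x2 tables, with
    Benjamini-Hochberg correction across terms.

    Terms with no observed individuals in either group are skipped.  The
    overall verdict is "no significant differences" when every adjusted
    q-value is >= alpha (or nothing was testable).
    """
    classes = m.mutation_class
    for label in CLASS_LABELS:
        if (classes == label).sum() == 0:
            raise ValueError(f"mutation class {label!r} absent from matrix")
    rows, skipped = [], []
    for term in m.terms:
        col = m.values[term]
        cells = {}
        empty_group = False
        for label in CLASS_LABELS:
            obs = col[classes == label].dropna()
            cells[label] = (int(obs.sum()), int(len(obs) - obs.sum()))
            if len(obs) == 0:
                empty_group = True
        if empty_group:
            skipped.append(term)
            continue
        table = [list(cells["lof"]), list(cells["missense"])]
        _, p = fisher_exact(table, alternative="two-sided")
        rows.append({
            "term": term,
            "lof_pos": cells["lof"][0], "lof_neg": cells["lof"][1],
            "missense_pos": cells["missense"][0],
            "missense_neg": cells["missense"][1],
            "p": float(p),
        })
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
        verdict = bool((df["q"] >= alpha).all())
    else:
        df = pd.DataFrame(columns=["term", "lof_pos", "lof_neg",
                                   "missense_pos", "missense_neg", "p", "q"])
        verdict = True
    return GroupComparison(df.set_index("term") if len(df) else df,
                           skipped, alpha, verdict)
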