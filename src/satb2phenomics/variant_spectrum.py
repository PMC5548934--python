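"""Variant-consequence classification and ORF constraint analysis for SATB2.

SATB2 (733 aa) carries three DNA-binding modules: two CUT domains
(aa 352-437 and 482-560) and a classic homeodomain (aa 614-677).  This module
classifies HGVS-like variant records into consequence classes, predicts
whether stop-introducing variants escape nonsense-mediated decay (NMD) by the
last-exon rule, predicts truncated protein products, computes a Gaussian
missense-density track along the ORF (the population-constraint view), and
detects variant-depleted intervals such as the untouched central portions of
the CUT domains.

The packaged study fixture (``load_study_variants``) transcribes the 19
distinct de novo variants of the source cohort: 2 essential-splice,
4 nonsense, 5 frameshift and 8 missense.  Note the cohort literature labels
the residue-566 variant both p.Glu566Lys and p.Gln566Lys; the fixture records
position 566 with the p.Gln566Lys spelling and does not resolve the residue
identity.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import norm

LOF_CLASSES = {"nonsense", "frameshift", "splice_donor", "splice_acceptor"}
STOP_INTRODUCING = {"nonsense", "frameshift"}
ALL_CLASSES = LOF_CLASSES | {"missense"}

#: domain labels reported for missense calls
DOMAIN_LABELS = ("CUT1", "CUT2", "HOX", "inter_CUT2_HOX", "other", "not_applicable")


@dataclass
class GeneModel:
    """ORF length, exon structure (codon units) and domain intervals."""

    protein_length: int
    exon_last_codon: list[int]  # last codon of each exon, strictly increasing
    domains: dict[str, tuple[int, int]]  # name -> inclusive aa interval
    chrom: str = ""
    genomic_start: int | None = None
    genomic_end: int | None = None

    def __post_init__(self) -> None:
        b = list(self.exon_last_codon)
        if any(y <= x for x, y in zip(b, b[1:])):
            raise ValueError("exon boundaries must be strictly increasing")
        if b[-1] != self.protein_length:
            raise ValueError("last exon must end at the final codon")
        for name, (lo, hi) in self.domains.items():
            if not (1 <= lo <= hi <= self.protein_length):
                raise ValueError(f"domain {name} outside [1, protein_length]")

    @property
    def n_exons(self) -> int:
        return len(self.exon_last_codon)

    def exon_of_codon(self, aa: int) -> int:
        """1-based exon index containing a codon position."""
        if not 1 <= aa <= self.protein_length:
            raise ValueError(f"codon {aa} outside ORF [1, {self.protein_length}]")
        return int(np.searchsorted(self.exon_last_codon, aa)) + 1

    def domain_of(self, aa: int) -> str:
        for name, (lo, hi) in self.domains.items():
            if lo <= aa <= hi:
                return name
        cut2 = self.domains.get("CUT2")
        hox = self.domains.get("HOX")
        if cut2 and hox and cut2[1] < aa < hox[0]:
            return "inter_CUT2_HOX"
        return "other"


@dataclass
class VariantRecord:
    id: str
    cdna: str
    raw_class: str
    protein: str = ""
    protein_pos: int | None = None
    exon: int | None = None

    def __post_init__(self) -> None:
        if self.raw_class not in ALL_CLASSES:
            raise ValueError(f"unknown consequence class {self.raw_class!r}")
        if self.raw_class == "missense" and self.protein_pos is None:
            raise ValueError(f"{self.id}: missense record requires protein_pos")
        if self.raw_class in ("splice_donor", "splice_acceptor"):
            intronic = "+" in self.cdna or "-" in self.cdna
            if not intronic and self.exon is None:
                raise ValueError(
                    f"{self.id}: splice record needs an intron boundary reference")


@dataclass
class ConsequenceCall:
    variant_id: str
    raw_class: str
    lof: bool
    nmd_escape: bool
    domain: str
    truncated_length: int | None = None
    domains_intact: bool | None = None


@dataclass
class DensityTrack:
    positions: np.ndarray  # aa grid 1..protein_length
    density: np.ndarray  # nonnegative; trapezoid-integrates to the variant count
    bandwidth: float


@dataclass
class SpectrumSummary:
    class_counts: dict[str, int]
    lof_total: int
    missense_by_domain: dict[str, int]
    n_variants: int
    cohort_percent: float | None = None
    cohort_counts: tuple[int, int] | None = None


# ---------------------------------------------------------------------------
# packaged fixtures


def load_gene_model() -> GeneModel:
    raw = json.loads(
        resources.files("satb2phenomics.data")
        .joinpath("gene_model_satb2.json").read_text()
    )
    return GeneModel(
        protein_length=raw["protein_length"],
        exon_last_codon=raw["exon_last_codon"],
        domains={k: tuple(v) for k, v in raw["domains"].items()},
        chrom=raw.get("chrom", ""),
        genomic_start=raw.get("genomic_start"),
        genomic_end=raw.get("genomic_end"),
    )


def variants_from_frame(df: pd.DataFrame) -> list[VariantRecord]:
    recs = []
    for _, row in df.iterrows():
        pos = row.get("protein_pos")
        exon = row.get("exon")
        recs.append(VariantRecord(
            id=str(row["id"]),
            cdna=str(row["cdna"]),
            raw_class=str(row["class"]),
            protein=str(row.get("protein", "")),
            protein_pos=None if pd.isna(pos) or pos in (".", "") else int(pos),
            exon=None if pd.isna(exon) or exon in (".", "") else int(exon),
        ))
    return recs


def load_study_variants() -> list[VariantRecord]:
    """The 19-variant study fixture (see module docstring for provenance)."""
    with resources.files("satb2phenomics.data").joinpath(
            "variants_satb2.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", na_values=["."])
    return variants_from_frame(df)


# ---------------------------------------------------------------------------
# classification


def classify_variant(v: VariantRecord, g: GeneModel,
                     penultimate_50nt: bool = False) -> ConsequenceCall:
    """Consequence call for one variant.

    Loss of function is any nonsense / frameshift / essential-splice class.
    NMD escape applies only to stop-introducing classes (nonsense,
    frameshift) and uses the last-exon rule: a variant located in the final
    exon is predicted to escape decay.  With ``penultimate_50nt`` the
    refinement extending escape to the last 50 nt of the penultimate exon is
    applied as well (off by default).  Domains are assigned for missense
    variants only.
    """
    lof = v.raw_class in LOF_CLASSES
    domain = "not_applicable"
    if v.raw_class == "missense":
        domain = g.domain_of(v.protein_pos)
    nmd_escape = False
    if v.raw_class in STOP_INTRODUCING:
        exon = v.exon if v.exon is not None else g.exon_of_codon(v.protein_pos)
        nmd_escape = exon == g.n_exons
        if penultimate_50nt and not nmd_escape and exon == g.n_exons - 1:
            junction_nt = g.exon_last_codon[-2] * 3
            pos_nt = 3 * (v.protein_pos if v.protein_pos else 0)
            nmd_escape = junction_nt - pos_nt <= 50
    return ConsequenceCall(v.id, v.raw_class, lof, nmd_escape, domain)


def predict_truncation(stop_codon_aa: int, g: GeneModel) -> ConsequenceCall:
    """Predicted product of a stop-gain at a given codon.

    The truncated protein retains residues 1..stop-1.  ``domains_intact`` is
    true when the stop lies beyond the end of the homeodomain, i.e. all three
    DNA-binding domains survive (e.g. a stop at codon 693 of 733 leaves a
    692-aa product lacking only the final 41 residues).
    """
    if not 1 < stop_codon_aa <= g.protein_length:
        raise ValueError("stop codon must lie in (1, protein_length]")
    exon = g.exon_of_codon(stop_codon_aa)
    hox_end = max(hi for _, hi in g.domains.values())
    return ConsequenceCall(
        variant_id=f"stop@{stop_codon_aa}",
        raw_class="nonsense",
        lof=True,
        nmd_escape=exon == g.n_exons,
        domain="not_applicable",
        truncated_length=stop_codon_aa - 1,
        domains_intact=stop_codon_aa > hox_end,
    )


# ---------------------------------------------------------------------------
# density and depletion


def missense_density(positions, g: GeneModel, bandwidth: float = 15.0
                     ) -> DensityTrack:
    """Gaussian-kernel density of missense positions along the ORF.

    Kernels are reflected at both ORF boundaries so no mass leaks outside
    [1, protein_length]; the track is rescaled to trapezoid-integrate to the
    number of input positions.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    grid = np.arange(1, g.protein_length + 1, dtype=float)
    positions = np.asarray(list(positions), dtype=float)
    if positions.size == 0:
        return DensityTrack(grid, np.zeros_like(grid), bandwidth)
    if positions.min() < 1 or positions.max() > g.protein_length:
        raise ValueError("positions outside [1, protein_length]")
    lo, hi = 1.0, float(g.protein_length)
    dens = np.zeros_like(grid)
    for p in positions:
        for center in (p, 2 * lo - p, 2 * hi - p):
            dens += norm.pdf(grid, loc=center, scale=bandwidth)
    integral = np.trapezoid(dens, grid)
    dens *= positions.size / integral
    return DensityTrack(grid, dens, bandwidth)


def find_depleted_intervals(positions, g: GeneModel, min_len: int = 25
                            ) -> list[dict]:
    """Maximal runs of >= min_len consecutive aa with no observed variant.

    Each interval is annotated with the domains it overlaps — the signature
    of purifying selection in population data (no population missense in the
    central portion of either CUT domain).
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    hit = np.zeros(g.protein_length + 1, dtype=bool)  # 1-based
    for p in positions:
        hit[int(p)] = True
    intervals = []
    start = None
    for aa in range(1, g.protein_length + 2):
        uncovered = aa <= g.protein_length and not hit[aa]
        if uncovered and start is None:
            start = aa
        elif not uncovered and start is not None:
            if aa - start >= min_len:
                lo, hi = start, aa - 1
                overlapping = [name for name, (dlo, dhi) in g.domains.items()
                               if not (hi < dlo or lo > dhi)]
                intervals.append({"start": lo, "end": hi, "domains": overlapping})
            start = None
    return intervals


def genomic_span_kb(start: int, end: int) -> float:
    """Span of a 1-based inclusive genomic interval, in kb to one decimal."""
    if end < start:
        raise ValueError("end must be >= start")
    return round((end - start + 1) / 1000.0, 1)


def summarize_spectrum(variants: list[VariantRecord], g: GeneModel,
                       cohort: tuple[int, int] | None = None
                       ) -> SpectrumSummary:
    """Class tallies, LoF total, missense-by-domain counts and optional
    cohort fraction (n_hit / n_total as a percentage to one decimal)."""
    calls = [classify_variant(v, g) for v in variants]
    class_counts = Counter(c.raw_class for c in calls)
    by_domain = Counter(c.domain for c in calls if c.raw_class == "missense")
    pct = counts = None
    if cohort is not None:
        n_hit, n_total = cohort
        if n_total == 0:
            raise ValueError("cohort n_total must be positive")
        pct = round(100.0 * n_hit / n_total, 1)
        counts = (n_hit, n_total)
    return SpectrumSummary(
        class_counts={k: class_counts.get(k, 0) for k in sorted(ALL_CLASSES)},
        lof_total=sum(1 for c in calls if c.lof),
        missense_by_domain=dict(by_domain),
        n_variants=len(variants),
        cohort_percent=pct,
        cohort_counts=counts,
    )
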