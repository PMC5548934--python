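"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators are provided:

* stylized face images with an exact 36-point landmark constellation,
  controllable left-right asymmetry and illumination variation
  (:func:`render_face`, :func:`make_cohort`);
* recurrent-photobleach fluorescence traces from a two-state
  (mobile/immobile) mono-exponential exchange model with pool depletion
  (:func:`simulate_flip`);
* HGVS-like variant tables over a gene model (:func:`make_variant_table`);
* Bernoulli phenotype matrices with per-individual mutation-class labels
  (:func:`make_phenotype_matrix`).

All randomness flows from the single integer seed passed to each call; there
is no hidden global state, and identical parameters plus an identical seed
give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage import draw as skdraw

from .face_geometry import (
    LandmarkConstellation,
    RoleMap,
    load_role_map,
    load_template,
)
from .flip_quant import FlipTrace
from .image import FaceImage
from .phenotype_stats import PhenotypeMatrix
from .variant_spectrum import GeneModel, VariantRecord

_TEMPLATE_FRAME = 200.0
MIN_IMAGE_SIZE = 128

# landmark indices used by the renderer (canonical layout; see role_map.json)
_FOREHEAD, _NASION, _NOSE_TIP, _UPPER_LIP, _LOWER_LIP, _CHIN = 0, 2, 3, 5, 6, 7
_BROW_L, _BROW_R = (8, 9, 10), (22, 23, 24)
_EYE_L, _EYE_R = (11, 12, 13, 14), (25, 26, 27, 28)
_ALA_L, _ALA_R = 15, 29
_MOUTH_L = (16, 17)  # corner, cupid
_MOUTH_R = (30, 31)
_OUTLINE = (0, 32, 33, 34, 35, 7, 21, 20, 19, 18)  # head outline, clockwise


# ---------------------------------------------------------------------------
# face parameters and landmark synthesis


@dataclass
class FaceParams:
    """Ground-truth parameters of one rendered face.

    ``feature_offsets`` (36 x 2, pixels) are applied *symmetrically*: each
    left/right pair shares the mirrored offset of its right member and
    midline points keep only their vertical component, so with
    ``asymmetry_shift = 0`` the rendered constellation is bilaterally
    mirror-exact about the midline.  ``asymmetry_shift`` then displaces the
    left-side landmarks horizontally by the given signed amount.
    """

    subject_id: str = "S0"
    feature_offsets: np.ndarray | None = None  # (36, 2) pixels
    asymmetry_shift: float = 0.0
    illumination: float = 1.0
    noise_sd: float = 0.0
    image_size: tuple[int, int] = (192, 192)  # (width, height)
    blur_sigma: float = 2.0  # template-frame px; photograph-like softness

    def __post_init__(self) -> None:
        if self.illumination <= 0:
            raise ValueError("illumination must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _symmetrize_offsets(offsets: np.ndarray, roles: RoleMap) -> np.ndarray:
    out = np.asarray(offsets, dtype=float).copy()
    out[roles.midline, 0] = 0.0
    for l, r in roles.pairs:
        dx, dy = out[r]
        out[r] = (dx, dy)
        out[l] = (-dx, dy)
    return out


def face_landmarks(params: FaceParams, roles: RoleMap | None = None
                   ) -> np.ndarray:
    """Exact landmark constellation for a parameter set (no rendering)."""
    roles = roles or load_role_map()
    w, h = params.image_size
    if w < MIN_IMAGE_SIZE or h < MIN_IMAGE_SIZE:
        raise ValueError(
            f"image_size {params.image_size} too small to contain a face; "
            f"need at least {MIN_IMAGE_SIZE}x{MIN_IMAGE_SIZE}")
    s = min(w, h) / _TEMPLATE_FRAME
    base = load_template()
    pts = np.empty_like(base)
    pts[:, 0] = w / 2.0 + (base[:, 0] - 100.0) * s
    pts[:, 1] = h / 2.0 + (base[:, 1] - 100.0) * s
    if params.feature_offsets is not None:
        offs = np.asarray(params.feature_offsets, dtype=float)
        if offs.shape != (36, 2):
            raise ValueError("feature_offsets must have shape (36, 2)")
        pts = pts + _symmetrize_offsets(offs, roles)
    pts[roles.left_indices, 0] += params.asymmetry_shift
    return pts


def _fill_polygon(img: np.ndarray, pts_xy: np.ndarray, value: float) -> None:
    rr, cc = skdraw.polygon(pts_xy[:, 1], pts_xy[:, 0], shape=img.shape)
    img[rr, cc] = value


def render_face(params: FaceParams, seed: int) -> FaceImage:
    """Render a stylized grayscale face from its landmark constellation.

    Features (head outline, brows, eyes, nose, mouth) are drawn as filled
    polygons/ellipses at the exact landmark positions, softened by a Gaussian
    blur, scaled by the illumination factor and perturbed by additive pixel
    noise.  The returned image carries the exact constellation used for
    rendering.
    """
    roles = load_role_map()
    pts = face_landmarks(params, roles)
    w, h = params.image_size
    s = min(w, h) / _TEMPLATE_FRAME
    img = np.full((h, w), 205.0)

    _fill_polygon(img, pts[list(_OUTLINE)], 172.0)
    for side in (_BROW_L, _BROW_R):
        brow = pts[list(side)]
        t = 2.0 * s
        band = np.vstack([brow + [0, -t], brow[::-1] + [0, t]])
        _fill_polygon(img, band, 60.0)
    for side in (_EYE_L, _EYE_R):
        inner, top, outer, bottom = pts[list(side)]
        cy = (top[1] + bottom[1]) / 2.0
        cx = (inner[0] + outer[0]) / 2.0
        rx = abs(outer[0] - inner[0]) / 2.0
        ry = abs(bottom[1] - top[1]) / 2.0
        rr, cc = skdraw.ellipse(cy, cx, max(ry, 1.0), max(rx, 1.0),
                                shape=img.shape)
        img[rr, cc] = 235.0
        rr, cc = skdraw.disk((cy, cx), max(0.7 * ry, 1.0), shape=img.shape)
        img[rr, cc] = 30.0
    _fill_polygon(img, pts[[_NASION, _ALA_L, _NOSE_TIP, _ALA_R]], 150.0)
    mouth = pts[[_MOUTH_L[0], _MOUTH_L[1], _UPPER_LIP,
                 _MOUTH_R[1], _MOUTH_R[0], _LOWER_LIP]]
    _fill_polygon(img, mouth, 90.0)

    if params.blur_sigma > 0:
        img = gaussian_filter(img, sigma=params.blur_sigma * s)
    img = img * params.illumination
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 255.0)
    return FaceImage(img, LandmarkConstellation(pts, params.subject_id, ""))


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortSpec:
    """Distribution of FaceParams across a cohort.

    Per subject (drawn once): feature offsets ~ N(0, offset_sd) per
    coordinate and an asymmetry shift ~ N(asymmetry_mean, asymmetry_sd).
    Per image (redrawn): illumination ~ lognormal(0, illumination_sd) and
    fresh pixel noise.
    """

    offset_sd: float = 2.0
    asymmetry_mean: float = 0.0
    asymmetry_sd: float = 0.0
    illumination_sd: float = 0.1
    noise_sd: float = 2.0
    image_size: tuple[int, int] = (192, 192)
    blur_sigma: float = 2.0


def _subject_params(spec: CohortSpec, rng: np.random.Generator,
                    subject_id: str) -> FaceParams:
    offsets = rng.normal(0.0, spec.offset_sd, size=(36, 2))
    shift = rng.normal(spec.asymmetry_mean, spec.asymmetry_sd)
    return FaceParams(subject_id=subject_id, feature_offsets=offsets,
                      asymmetry_shift=float(shift), noise_sd=spec.noise_sd,
                      image_size=spec.image_size, blur_sigma=spec.blur_sigma)


def sample_constellations(n_subjects: int, spec: CohortSpec, seed: int
                          ) -> list[LandmarkConstellation]:
    """One ground-truth constellation per subject, without rendering.

    Cheap path for target-mesh construction at population scale.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    roles = load_role_map()
    out = []
    for i in range(n_subjects):
        p = _subject_params(spec, rng, f"S{i:04d}")
        out.append(LandmarkConstellation(face_landmarks(p, roles),
                                         p.subject_id, f"{p.subject_id}_img0"))
    return out


def make_cohort(n_subjects: int, images_per_subject: int, spec: CohortSpec,
                seed: int) -> list[FaceImage]:
    """Render a multi-image-per-subject cohort.

    Subject identity (offsets, asymmetry) is stable across a subject's
    images; illumination and noise are redrawn per image.
    """
    if n_subjects < 1 or images_per_subject < 1:
        raise ValueError("need n_subjects >= 1 and images_per_subject >= 1")
    rng = np.random.default_rng(seed)
    faces = []
    for i in range(n_subjects):
        base = _subject_params(spec, rng, f"S{i:04d}")
        for j in range(images_per_subject):
            illum = float(np.exp(rng.normal(0.0, spec.illumination_sd)))
            p = replace(base, illumination=illum)
            face = render_face(p, seed=int(rng.integers(2**31)))
            face.constellation.image_id = f"{p.subject_id}_img{j}"
            faces.append(face)
    return faces


# ---------------------------------------------------------------------------
# photobleach traces


@dataclass
class FlipParams:
    """Two-state photobleach model parameters.

    A fraction ``mobile_fraction`` of the pre-bleach ROI signal exchanges
    with the nucleoplasmic pool at rate ``k_rec``; the rest is immobile.
    Each bleach event destroys ``bleach_depth`` of the current ROI signal;
    the bleached mobile share depletes the exchanging pool in proportion to
    ``roi_fraction`` (the ROI's share of the pool volume).  Between events
    the ROI recovers mono-exponentially toward
    ``immobile_remaining + pool_current``.
    """

    mobile_fraction: float = 0.5
    k_rec: float = 0.5  # 1/s
    bleach_depth: float = 0.8
    n_cycles: int = 6
    dwell: float = 20.0  # s of recovery per cycle
    dt: float = 0.25  # s sampling interval
    noise_sd: float = 0.0  # relative (multiplicative) intensity noise
    roi_fraction: float = 0.1
    pre_bleach_s: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mobile_fraction <= 1.0:
            raise ValueError("mobile_fraction must be in [0, 1]")
        if self.k_rec <= 0:
            raise ValueError("k_rec must be > 0")
        if not 0.0 <= self.bleach_depth <= 1.0:
            raise ValueError("bleach_depth must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 < self.roi_fraction <= 1.0:
            raise ValueError("roi_fraction must be in (0, 1]")


def simulate_flip(params: FlipParams, seed: int, cell_id: str = "",
                  construct: str = "") -> FlipTrace:
    """Simulate one recurrent-photobleach trace.

    Pre-bleach ROI fluorescence is 1.  State: immobile ROI signal I
    (initially 1 - mobile_fraction), ROI mobile signal M (initially
    mobile_fraction) and pool level c (initially mobile_fraction).  At each
    bleach event I and M drop by the bleach depth d and the pool loses the
    bleached mobile share scaled by the ROI volume fraction
    (c -= roi_fraction * d * M).  Between events
    F(t) = (I + c) - ((I + c) - F_post) * exp(-k_rec * t).  Multiplicative
    Gaussian noise is applied per sample; event sample indices are recorded.
    """
    p = params
    rng = np.random.default_rng(seed)
    n_pre = max(1, round(p.pre_bleach_s / p.dt))
    n_dwell = max(4, round(p.dwell / p.dt))
    d = p.bleach_depth
    immobile = 1.0 - p.mobile_fraction
    mobile = p.mobile_fraction
    pool = p.mobile_fraction
    values = [1.0] * n_pre
    events = []
    for _ in range(p.n_cycles):
        pool -= p.roi_fraction * d * mobile
        immobile *= 1.0 - d
        mobile *= 1.0 - d
        events.append(len(values))
        plateau = immobile + pool
        f_post = immobile + mobile
        tau = np.arange(n_dwell) * p.dt
        seg = plateau - (plateau - f_post) * np.exp(-p.k_rec * tau)
        values.extend(seg.tolist())
        mobile = float(seg[-1]) - immobile
    intensity = np.asarray(values)
    if p.noise_sd > 0:
        intensity = intensity * (1.0 + rng.normal(0.0, p.noise_sd,
                                                  size=intensity.shape))
    intensity = np.maximum(intensity, 0.0)
    time_s = np.arange(len(intensity)) * p.dt
    return FlipTrace(time_s, intensity, np.asarray(events, dtype=int),
                     cell_id=cell_id, construct=construct)


def construct_panel(noise_sd: float = 0.02) -> dict[str, FlipParams]:
    """Simulation analogs of the study's four photobleached constructs.

    Mobile fractions 0.8 (CUT1 missense analog), 0.5 (wild type) and 0.2
    (CUT2 and inter-domain analogs); the low-mobility analogs also recover
    more slowly.  These are the study conditions for the qualitative
    mobility ordering: highest residual with near-wild-type recovery for the
    CUT1 analog, deepest loss and slowest recovery for the low-mobility
    analogs.
    """
    base = dict(bleach_depth=0.8, n_cycles=6, dwell=20.0, dt=0.25,
                noise_sd=noise_sd)
    return {
        "WT": FlipParams(mobile_fraction=0.5, k_rec=0.5, **base),
        "R389C_CUT1": FlipParams(mobile_fraction=0.8, k_rec=0.5, **base),
        "G515S_CUT2": FlipParams(mobile_fraction=0.2, k_rec=0.15, **base),
        "Q566K_interdomain": FlipParams(mobile_fraction=0.2, k_rec=0.15,
                                        **base),
    }


# ---------------------------------------------------------------------------
# variant tables


_AA3 = ["Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
        "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val"]


def make_variant_table(gene: GeneModel, n_lof: int, n_missense: int,
                       seed: int) -> list[VariantRecord]:
    """Random legal variant records over a gene model.

    LoF records are drawn uniformly over {nonsense, frameshift, splice_donor,
    splice_acceptor}; coordinates are uniform over legal positions (codons
    inside the ORF; splice variants at internal exon boundaries).
    """
    if n_lof < 0 or n_missense < 0:
        raise ValueError("variant counts must be >= 0")
    rng = np.random.default_rng(seed)
    recs: list[VariantRecord] = []
    lof_classes = ["nonsense", "frameshift", "splice_donor", "splice_acceptor"]
    k = 0
    for _ in range(n_lof):
        cls = lof_classes[int(rng.integers(len(lof_classes)))]
        k += 1
        if cls in ("splice_donor", "splice_acceptor"):
            b = int(rng.integers(1, gene.n_exons))  # internal boundary index
            last_nt = gene.exon_last_codon[b - 1] * 3
            if cls == "splice_donor":
                cdna, exon = f"c.{last_nt}+1G>A", b
            else:
                cdna, exon = f"c.{last_nt + 1}-2A>G", b + 1
            recs.append(VariantRecord(f"SYN{k:03d}", cdna, cls, exon=exon))
        else:
            pos = int(rng.integers(2, gene.protein_length))
            aa = _AA3[int(rng.integers(len(_AA3)))]
            if cls == "nonsense":
                cdna = f"c.{3 * pos - 2}C>T"
                protein = f"p.{aa}{pos}Ter"
            else:
                cdna = f"c.{3 * pos - 2}del"
                protein = f"p.{aa}{pos}fs"
            recs.append(VariantRecord(f"SYN{k:03d}", cdna, cls,
                                      protein=protein, protein_pos=pos,
                                      exon=gene.exon_of_codon(pos)))
    for _ in range(n_missense):
        k += 1
        pos = int(rng.integers(2, gene.protein_length))
        ref, alt = rng.choice(_AA3, size=2, replace=False)
        recs.append(VariantRecord(
            f"SYN{k:03d}", f"c.{3 * pos - 2}G>A", "missense",
            protein=f"p.{ref}{pos}{alt}", protein_pos=pos,
            exon=gene.exon_of_codon(pos)))
    return recs


def variant_table_to_frame(recs: list[VariantRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "id": r.id, "cdna": r.cdna, "protein": r.protein or ".",
        "class": r.raw_class,
        "protein_pos": r.protein_pos if r.protein_pos is not None else ".",
        "exon": r.exon if r.exon is not None else ".",
    } for r in recs])


# ---------------------------------------------------------------------------
# phenotype matrices


def make_phenotype_matrix(n_individuals: int, term_prevalences: dict,
                          class_labels: list, seed: int) -> PhenotypeMatrix:
    """Bernoulli phenotype matrix with a mutation-class label per individual."""
    if len(class_labels) != n_individuals:
        raise ValueError("class_labels length must equal n_individuals")
    for term, p in term_prevalences.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"prevalence for {term!r} outside [0, 1]")
    rng = np.random.default_rng(seed)
    ids = [f"I{i:03d}" for i in range(n_individuals)]
    data = {term: (rng.random(n_individuals) < p).astype(float)
            for term, p in term_prevalences.items()}
    values = pd.DataFrame(data, index=ids)
    classes = pd.Series(list(class_labels), index=ids, name="mutation_class")
    return PhenotypeMatrix(values, classes)
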