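"""Quantitative and qualitative evaluation apparatus.

* :func:`auc_mann_whitney` — AUC as the Mann–Whitney pair statistic (ties get
  half credit) together with the empirical ROC curve, whose trapezoidal area
  equals the pair statistic.
* :func:`delong_test` — the DeLong comparison of two correlated AUCs computed
  on the same cases, via placement-value covariances and a two-sided normal
  p-value.
* :func:`paired_t_test` — classical paired t for rating tables.
* :func:`evaluate_cohort` — the end-to-end harness: DRR per technique →
  display mapping → 224×224 bicubic resize → pluggable scorer → ROC/AUC and
  all pairwise DeLong comparisons.

The scorer is a plain callable from a 224×224 display image to a real score,
replacing the trained chest-radiograph classifier the procedure was designed
around.  Three reference scorers ship with the module: a nodule-conspicuity
detector (default), a lung-field mean intensity baseline, and a random null.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import uniform_filter

from .core import CTVolume, DataError, DegenerateLabelsError, DrrForgeError
from .phantom import CohortCase, PhantomSpec, generate_chest_phantom
from .pipeline import NoiseParams, generate_drr
from .postprocess import intensity_to_display, resize_bicubic

logger = logging.getLogger(__name__)

__all__ = [
    "RocResult",
    "DeLongResult",
    "PairedTResult",
    "DegenerateVarianceError",
    "auc_mann_whitney",
    "delong_test",
    "delong_variance",
    "paired_t_test",
    "evaluate_cohort",
    "EvaluationReport",
    "conspicuity_scorer",
    "roi_mean_scorer",
    "make_null_scorer",
    "get_scorer",
]

DEFAULT_TECHNIQUES = ("beer_lambert", "softmip", "wedge", "point_source")


class DegenerateVarianceError(DrrForgeError, ValueError):
    """DeLong variance of the AUC difference is zero while the AUCs differ."""


@dataclass(frozen=True)
class RocResult:
    """AUC with its empirical ROC curve and class counts."""

    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class DeLongResult:
    auc1: float
    auc2: float
    var_diff: float
    z: float
    p: float


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float


def _split_labels(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise DataError("scores and labels must be 1D arrays of equal length")
    if not np.all(np.isin(labels, (0, 1))):
        raise DataError("labels must be binary (0/1)")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise DegenerateLabelsError("ROC analysis needs at least one positive and one negative")
    return pos, neg


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong placement values (V10 per positive, V01 per negative) and AUC."""
    pos, neg = _split_labels(scores, labels)
    m, n = len(pos), len(neg)
    combined = np.concatenate([pos, neg])
    r_all = stats.rankdata(combined)
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    v10 = (r_all[:m] - r_pos) / n  # fraction of negatives below each positive
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    auc = float(v10.mean())
    return v10, v01, auc


def _roc_points(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical ROC curve from (0,0) to (1,1), one point per distinct threshold."""
    scores = np.concatenate([pos, neg])
    y = np.concatenate([np.ones(len(pos), dtype=int), np.zeros(len(neg), dtype=int)])
    order = np.argsort(-scores, kind="mergesort")
    scores, y = scores[order], y[order]
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    # keep the last index of each tie block
    distinct = np.r_[np.diff(scores) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / len(pos)]
    fpr = np.r_[0.0, fps[distinct] / len(neg)]
    return fpr, tpr


def auc_mann_whitney(scores, labels) -> RocResult:
    """AUC as the Mann–Whitney statistic over all positive/negative pairs.

    A pair scores 1 when the positive outranks the negative and 0.5 on a tie;
    the result equals the trapezoidal area under the empirical ROC curve.
    Raises :class:`DegenerateLabelsError` when a class is missing.
    """
    _, _, auc = _placements(np.asarray(scores, dtype=float), np.asarray(labels))
    pos, neg = _split_labels(np.asarray(scores, dtype=float), np.asarray(labels))
    fpr, tpr = _roc_points(pos, neg)
    return RocResult(auc=auc, fpr=fpr, tpr=tpr, n_pos=len(pos), n_neg=len(neg))


def delong_variance(scores, labels) -> float:
    """DeLong variance estimate of a single AUC."""
    v10, v01, _ = _placements(np.asarray(scores, dtype=float), np.asarray(labels))
    m, n = len(v10), len(v01)
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    return s10 / m + s01 / n


def delong_test(scores_a, scores_b, labels) -> DeLongResult:
    """DeLong test for two correlated AUCs measured on the same cases.

    Computes placement values per score vector, their covariance across
    cases, and ``z = (AUC_a − AUC_b) / sqrt(var)`` with a two-sided normal
    p-value.  Identical placement structures give ``z = 0, p = 1`` exactly;
    zero variance with differing AUCs raises
    :class:`DegenerateVarianceError`.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise DataError("both score vectors must cover the same cases")
    labels = np.asarray(labels)
    v10a, v01a, auc_a = _placements(scores_a, labels)
    v10b, v01b, auc_b = _placements(scores_b, labels)
    m, n = len(v10a), len(v01a)

    s10 = np.cov(np.stack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var_diff = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    var_diff = float(max(var_diff, 0.0))

    diff = auc_a - auc_b
    if var_diff <= 1e-300:
        if abs(diff) <= 1e-12:
            return DeLongResult(auc1=auc_a, auc2=auc_b, var_diff=0.0, z=0.0, p=1.0)
        raise DegenerateVarianceError(
            f"zero DeLong variance with differing AUCs ({auc_a:.4f} vs {auc_b:.4f})"
        )
    z = diff / math.sqrt(var_diff)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return DeLongResult(auc1=auc_a, auc2=auc_b, var_diff=var_diff, z=z, p=p)


def paired_t_test(x, y) -> PairedTResult:
    """Classical two-sided paired t-test on ``d = x − y`` with ``df = n − 1``.

    Zero-variance differences: all-zero ``d`` returns ``t = 0, p = 1``;
    constant nonzero ``d`` is reported as ``p = 0`` with infinite ``t``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("paired t-test needs two equal-length 1D vectors")
    n = len(x)
    if n < 2:
        raise DataError("paired t-test needs at least two pairs")
    d = x - y
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0.0:
        if mean == 0.0:
            return PairedTResult(t=0.0, df=n - 1, p=1.0)
        return PairedTResult(t=math.copysign(math.inf, mean), df=n - 1, p=0.0)
    t = mean / (sd / math.sqrt(n))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return PairedTResult(t=float(t), df=n - 1, p=p)


# ---------------------------------------------------------------------------
# Reference scorers
# ---------------------------------------------------------------------------

# Lung-field geometry of the phantom DRR as fractions of image size: the two
# lung ellipses sit at ±0.22 of the width with half-axes (0.36 H, 0.15 W).
_LUNG_CENTERS_X = (0.5 - 0.22, 0.5 + 0.22)
_LUNG_HALF_AXES = (0.36, 0.15)


def _lung_field_mask(shape: tuple[int, int], rmax: float = 0.85) -> np.ndarray:
    h, w = shape
    zz, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros(shape, dtype=bool)
    for cx in _LUNG_CENTERS_X:
        d = ((zz - 0.5 * h) / (_LUNG_HALF_AXES[0] * h)) ** 2 + (
            (xx - cx * w) / (_LUNG_HALF_AXES[1] * w)
        ) ** 2
        mask |= d <= rmax**2
    return mask


def roi_mean_scorer(image: np.ndarray) -> float:
    """Mean display intensity over the lung-field regions.

    The simplest surrogate reader: sensitive to anything that brightens the
    lung fields, but also to overall anatomy size, so it is a weak nodule
    detector (see the methods note); shipped as the transparency baseline.
    """
    image = np.asarray(image, dtype=float)
    return float(image[_lung_field_mask(image.shape)].mean())


def conspicuity_scorer(image: np.ndarray, nodule_mm: float = 8.0, fov_mm: float = 192.0) -> float:
    """Bilateral-asymmetry nodule conspicuity within the lung fields.

    Subtracts the left-right mirrored image (the standard chest-CAD symmetry
    heuristic: normal thoracic anatomy is near-symmetric, a unilateral nodule
    is not), smooths the difference with a nodule-sized mean filter, and
    returns the maximum absolute asymmetry inside the lung fields.  On the
    symmetric phantom cohort this isolates the lesion signal from ribs, spine
    and body outline, which cancel in the mirror difference.
    """
    image = np.asarray(image, dtype=float)
    k = max(3, int(round(nodule_mm * image.shape[1] / fov_mm)))
    asym = uniform_filter(image - image[:, ::-1], size=k, mode="nearest")
    return float(np.abs(asym[_lung_field_mask(image.shape)]).max())


def make_null_scorer(seed: int = 0) -> Callable[[np.ndarray], float]:
    """A scorer that ignores the image and returns seeded uniform noise."""
    rng = np.random.default_rng(seed)

    def _score(_image: np.ndarray) -> float:
        return float(rng.random())

    return _score


def get_scorer(name: str, seed: int = 0) -> Callable[[np.ndarray], float]:
    """Look up a shipped scorer by name: conspicuity | roi-mean | null."""
    if name == "conspicuity":
        return conspicuity_scorer
    if name in ("roi-mean", "roi_mean"):
        return roi_mean_scorer
    if name == "null":
        return make_null_scorer(seed)
    raise DataError(f"unknown scorer {name!r}")


# ---------------------------------------------------------------------------
# Cohort harness
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Per-technique ROC results, raw scores, and pairwise DeLong comparisons."""

    techniques: List[str]
    case_ids: List[str]
    labels: np.ndarray
    scores: Dict[str, np.ndarray]
    roc: Dict[str, RocResult]
    delong: Dict[Tuple[str, str], DeLongResult]

    def auc(self, technique: str) -> float:
        return self.roc[technique].auc

    def to_dict(self) -> dict:
        return {
            "techniques": {
                t: {
                    "auc": self.roc[t].auc,
                    "n_pos": self.roc[t].n_pos,
                    "n_neg": self.roc[t].n_neg,
                    "roc": {
                        "fpr": self.roc[t].fpr.tolist(),
                        "tpr": self.roc[t].tpr.tolist(),
                    },
                }
                for t in self.techniques
            },
            "delong": [
                {
                    "technique_a": a,
                    "technique_b": b,
                    "auc_a": r.auc1,
                    "auc_b": r.auc2,
                    "z": r.z,
                    "p": r.p,
                }
                for (a, b), r in self.delong.items()
            ],
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_csv(self, path) -> None:
        rows = [
            {"technique": t, "auc": self.roc[t].auc, "n_pos": self.roc[t].n_pos, "n_neg": self.roc[t].n_neg}
            for t in self.techniques
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    def scores_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"case_id": self.case_ids, "label": self.labels})
        for t in self.techniques:
            frame[t] = self.scores[t]
        return frame


CaseLike = Union[CohortCase, Tuple[str, Union[CTVolume, PhantomSpec], int]]


def _realize(case: CaseLike) -> tuple[str, CTVolume, int]:
    if isinstance(case, CohortCase):
        return case.case_id, case.volume(), case.label
    case_id, payload, label = case
    if isinstance(payload, PhantomSpec):
        payload = generate_chest_phantom(payload)
    return str(case_id), payload, int(label)


def _load_manifest(path) -> List[Tuple[str, CTVolume, int]]:
    from . import io_formats

    frame = pd.read_csv(path)
    required = {"case_id", "path", "label"}
    if not required.issubset(frame.columns):
        raise DataError(f"manifest must have columns {sorted(required)}")
    base = Path(path).parent
    cases = []
    for row in frame.itertuples(index=False):
        vol_path = Path(row.path)
        if not vol_path.is_absolute():
            vol_path = base / vol_path
        cases.append((str(row.case_id), io_formats.read_nifti(vol_path), int(row.label)))
    return cases


def evaluate_cohort(
    cases: Union[str, Path, Iterable[CaseLike]],
    techniques: Sequence[str] = DEFAULT_TECHNIQUES,
    scorer: Optional[Callable[[np.ndarray], float]] = None,
    *,
    seed: int = 0,
    noise: Optional[dict] = None,
    display_mode: str = "neg_log",
    resize: int = 224,
) -> EvaluationReport:
    """Score every case with every technique and compare the ROC curves.

    For each case and technique: generate the DRR, map to display, resize to
    ``resize × resize`` with bicubic interpolation, and apply the scorer.
    Cases whose scorer output is NaN are dropped (with a warning) from every
    technique so the DeLong comparisons stay paired.  Noise (default: photon
    noise at 10⁵ photons/pixel with 10% scatter) applies to the point-source
    technique, seeded per case from ``seed``.
    """
    if isinstance(cases, (str, Path)):
        cases = _load_manifest(cases)
    scorer = scorer or conspicuity_scorer
    if noise is None:
        noise = NoiseParams.default()

    rng = np.random.default_rng(seed)
    case_ids: List[str] = []
    labels: List[int] = []
    raw_scores: Dict[str, List[float]] = {t: [] for t in techniques}

    n_cases = 0
    for case in cases:
        case_id, volume, label = _realize(case)
        n_cases += 1
        noise_seed = int(rng.integers(0, 2**31 - 1))
        row: Dict[str, float] = {}
        ok = True
        for technique in techniques:
            drr = generate_drr(
                volume,
                technique,
                noise=noise if technique == "point_source" else None,
                noise_seed=noise_seed,
            )
            display = intensity_to_display(drr, mode=display_mode)
            img = resize_bicubic(display, size=resize)
            score = float(scorer(np.asarray(img.data)))
            if math.isnan(score):
                logger.warning("scorer returned NaN for case %s / %s; case excluded", case_id, technique)
                ok = False
                break
            row[technique] = score
        if not ok:
            continue
        case_ids.append(case_id)
        labels.append(label)
        for technique in techniques:
            raw_scores[technique].append(row[technique])

    if n_cases == 0:
        raise DataError("the cohort is empty")

    label_arr = np.asarray(labels, dtype=int)
    scores = {t: np.asarray(v, dtype=float) for t, v in raw_scores.items()}
    roc = {t: auc_mann_whitney(scores[t], label_arr) for t in techniques}
    delong: Dict[Tuple[str, str], DeLongResult] = {}
    for i, a in enumerate(techniques):
        for b in techniques[i:]:
            delong[(a, b)] = delong_test(scores[a], scores[b], label_arr)

    return EvaluationReport(
        techniques=list(techniques),
        case_ids=case_ids,
        labels=label_arr,
        scores=scores,
        roc=roc,
        delong=delong,
    )
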