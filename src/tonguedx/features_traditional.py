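"""Traditional (hand-crafted) tongue-image features and tabular preprocessing.

Color is summarized in CIELAB (D65 white point): mean and standard deviation
of L*, a*, b* over the masked tongue pixels.  Texture is summarized by
gray-level co-occurrence matrix (GLCM) statistics computed **inside the
mask**: the image is converted to gray, quantized to ``levels`` bins over the
masked intensity range, and pixel pairs at each (distance, angle) offset are
counted only when both ends lie in the mask; the matrix is symmetrized and
normalized, and the five statistics (ASM, contrast, correlation, homogeneity,
entropy) are averaged over the configured offsets.

The module also provides the tabular plumbing around those features:
one-hot encoding of categorical physician annotations, leakage-safe
standardization, binary-column validation with mode imputation, and Fleiss'
kappa for inter-rater agreement (via statsmodels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.color import rgb2gray, rgb2lab
from statsmodels.stats.inter_rater import aggregate_raters
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss

__all__ = [
    "LabStats",
    "GLCMFeatures",
    "AnnotationRecord",
    "ANNOTATION_VOCABULARY",
    "FeatureTable",
    "lab_stats",
    "glcm_features",
    "one_hot",
    "standardize",
    "validate_binary",
    "fleiss_kappa",
    "extract_feature_table",
    "GLCM_DEFAULT_ANGLES",
]

GLCM_DEFAULT_ANGLES = (0.0, 45.0, 90.0, 135.0)


@dataclass(frozen=True)
class LabStats:
    mean_L: float
    mean_a: float
    mean_b: float
    std_L: float
    std_a: float
    std_b: float

    def as_dict(self) -> dict[str, float]:
        return {
            "lab_mean_L": self.mean_L, "lab_mean_a": self.mean_a, "lab_mean_b": self.mean_b,
            "lab_std_L": self.std_L, "lab_std_a": self.std_a, "lab_std_b": self.std_b,
        }


@dataclass(frozen=True)
class GLCMFeatures:
    asm: float
    contrast: float
    correlation: float
    homogeneity: float
    entropy: float

    def as_dict(self) -> dict[str, float]:
        return {
            "glcm_asm": self.asm, "glcm_contrast": self.contrast,
            "glcm_correlation": self.correlation, "glcm_homogeneity": self.homogeneity,
            "glcm_entropy": self.entropy,
        }


#: Default label vocabularies for physician annotations of tongue appearance.
ANNOTATION_VOCABULARY: dict[str, tuple[str, ...]] = {
    "tongue_color": ("pale", "pink", "red", "dark_red", "purple"),
    "tongue_shape": ("normal", "enlarged", "thin", "cracked", "tooth_marked"),
    "coating_color": ("white", "yellow", "gray", "black"),
    "coating_texture": ("thin", "thick", "greasy", "peeled"),
}


@dataclass(frozen=True)
class AnnotationRecord:
    """One rater's categorical annotation of a tongue image."""

    tongue_color: str
    tongue_shape: str
    coating_color: str
    coating_texture: str

    def __post_init__(self):
        for aspect, vocab in ANNOTATION_VOCABULARY.items():
            value = getattr(self, aspect)
            if value not in vocab:
                raise ValueError(
                    f"{aspect} label {value!r} not in vocabulary {vocab}"
                )

    def as_dict(self) -> dict[str, str]:
        return {k: getattr(self, k) for k in ANNOTATION_VOCABULARY}


@dataclass
class FeatureTable:
    """Samples x named features with a per-feature kind.

    kinds maps feature name -> 'continuous' | 'categorical' | 'binary'.
    """

    values: pd.DataFrame
    kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.kinds) - set(self.values.columns)
        if unknown:
            raise ValueError(f"kinds refer to unknown columns: {sorted(unknown)}")
        for c in self.values.columns:
            self.kinds.setdefault(c, "continuous")

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    def columns_of_kind(self, kind: str) -> list[str]:
        return [c for c in self.values.columns if self.kinds[c] == kind]

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="sample_id")

    @classmethod
    def from_csv(cls, path, kinds: dict[str, str] | None = None) -> "FeatureTable":
        df = pd.read_csv(path, index_col="sample_id")
        return cls(df, kinds or {})


# --------------------------------------------------------------------------
# color
# --------------------------------------------------------------------------


def lab_stats(image: np.ndarray, mask: np.ndarray) -> LabStats:
    """CIELAB statistics over masked pixels (sRGB input, D65 illuminant)."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    lab = rgb2lab(np.asarray(image, dtype=np.float64) / 255.0)
    sel = lab[mask]
    means = sel.mean(axis=0)
    stds = sel.std(axis=0)
    return LabStats(*(float(v) for v in means), *(float(v) for v in stds))


# --------------------------------------------------------------------------
# texture
# --------------------------------------------------------------------------


def _angle_offset(distance: int, angle_deg: float) -> tuple[int, int]:
    """(row, col) offset for a co-occurrence direction.

    0 deg is rightwards along a row; angles rotate counter-clockwise in image
    coordinates (so 90 deg pairs pixels within a column).
    """
    th = np.deg2rad(angle_deg)
    dr = -int(round(distance * np.sin(th)))
    dc = int(round(distance * np.cos(th)))
    return dr, dc


def _quantize(gray: np.ndarray, mask: np.ndarray, levels: int) -> np.ndarray:
    vals = gray[mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        return np.zeros_like(gray, dtype=np.int64)
    q = np.floor((gray - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def _cooccurrence(q: np.ndarray, mask: np.ndarray, dr: int, dc: int, levels: int) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix; pairs must lie in-mask."""
    h, w = q.shape
    r0 = max(0, -dr)
    r1 = min(h, h - dr)
    c0 = max(0, -dc)
    c1 = min(w, w - dc)
    a = q[r0:r1, c0:c1]
    b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    valid = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    mat = np.zeros((levels, levels), dtype=np.float64)
    np.add.at(mat, (a[valid], b[valid]), 1.0)
    mat = mat + mat.T  # symmetric counting
    total = mat.sum()
    return mat / total if total > 0 else mat


def _glcm_stats(p: np.ndarray) -> dict[str, float]:
    levels = p.shape[0]
    i, j = np.meshgrid(np.arange(levels), np.arange(levels), indexing="ij")
    asm = float((p**2).sum())
    contrast = float(((i - j) ** 2 * p).sum())
    homogeneity = float((p / (1.0 + (i - j) ** 2)).sum())
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    var_i = float(((i - mu_i) ** 2 * p).sum())
    var_j = float(((j - mu_j) ** 2 * p).sum())
    if var_i > 0 and var_j > 0:
        corr = float((((i - mu_i) * (j - mu_j) * p).sum()) / np.sqrt(var_i * var_j))
    else:
        corr = 1.0  # degenerate single-level matrix: perfect correlation
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return {"asm": asm, "contrast": contrast, "correlation": corr,
            "homogeneity": homogeneity, "entropy": entropy}


def glcm_features(
    image: np.ndarray,
    mask: np.ndarray,
    distances: tuple[int, ...] = (1,),
    angles: tuple[float, ...] = GLCM_DEFAULT_ANGLES,
    levels: int = 32,
) -> GLCMFeatures:
    """Masked GLCM statistics averaged over (distance, angle) offsets."""
    mask = np.asarray(mask).astype(bool)
    if mask.sum() < 2:
        raise ValueError("mask must cover at least 2 pixels")
    if levels < 2:
        raise ValueError("levels must be >= 2")
    img = np.asarray(image)
    gray = rgb2gray(img / 255.0) if img.ndim == 3 else img.astype(np.float64)
    q = _quantize(gray, mask, levels)
    stats: list[dict[str, float]] = []
    for d in distances:
        for ang in angles:
            dr, dc = _angle_offset(d, ang)
            p = _cooccurrence(q, mask, dr, dc, levels)
            if p.sum() == 0:  # no in-mask pair at this offset
                continue
            stats.append(_glcm_stats(p))
    if not stats:
        # single-pixel-like degenerate region: uniform by convention
        return GLCMFeatures(1.0, 0.0, 1.0, 1.0, 0.0)
    mean = {k: float(np.mean([s[k] for s in stats])) for k in stats[0]}
    return GLCMFeatures(**mean)


# --------------------------------------------------------------------------
# tabular preprocessing
# --------------------------------------------------------------------------


def one_hot(
    column: pd.Series, vocabulary: list[str] | None = None
) -> pd.DataFrame:
    """Expand a categorical column into one binary column per category.

    No reference category is dropped: each row sums to exactly 1.  Values not
    in the (given or inferred) vocabulary are rejected by name.
    """
    vocab = sorted(set(column)) if vocabulary is None else list(vocabulary)
    unseen = set(column) - set(vocab)
    if unseen:
        raise ValueError(f"unseen categories at transform time: {sorted(unseen)}")
    out = pd.DataFrame(
        {f"{column.name}={v}": (column == v).astype(int) for v in vocab},
        index=column.index,
    )
    return out


def one_hot_decode(encoded: pd.DataFrame, name: str) -> pd.Series:
    """Inverse of :func:`one_hot` for the given original column name."""
    cols = [c for c in encoded.columns if c.startswith(f"{name}=")]
    cats = [c.split("=", 1)[1] for c in cols]
    idx = encoded[cols].values.argmax(axis=1)
    return pd.Series([cats[i] for i in idx], index=encoded.index, name=name)


@dataclass(frozen=True)
class StandardizeParams:
    mean: pd.Series
    std: pd.Series


def standardize(
    table: FeatureTable, fit_ids: list | None = None
) -> tuple[FeatureTable, StandardizeParams]:
    """Zero-mean / unit-variance scale continuous columns.

    Parameters are estimated on ``fit_ids`` only (all rows when omitted) and
    applied to every row — the held-out rows never influence the fit.
    Zero-variance columns are centered and passed through with a warning.
    """
    cont = table.columns_of_kind("continuous")
    df = table.values.copy()
    fit_ids = table.sample_ids if fit_ids is None else list(fit_ids)
    if not fit_ids:
        raise ValueError("empty fit set")
    fit = df.loc[fit_ids, cont]
    mean = fit.mean()
    std = fit.std(ddof=0)
    zero_var = std[std == 0].index.tolist()
    if zero_var:
        warnings.warn(f"zero-variance columns centered only: {zero_var}")
        std = std.replace(0.0, 1.0)
    df[cont] = (df[cont] - mean) / std
    return FeatureTable(df, dict(table.kinds)), StandardizeParams(mean, std)


@dataclass
class BinaryAudit:
    imputed: dict[str, int] = field(default_factory=dict)
    out_of_set: dict[str, list] = field(default_factory=dict)


def validate_binary(
    table: FeatureTable, default: int = 0
) -> tuple[FeatureTable, BinaryAudit]:
    """Coerce binary-kind columns to {0,1}: mode-impute missing values and
    replace out-of-set values with ``default`` (audited)."""
    df = table.values.copy()
    audit = BinaryAudit()
    for col in table.columns_of_kind("binary"):
        s = df[col]
        if s.isna().all():
            raise ValueError(f"binary column {col!r} has no observed values")
        bad = s.dropna()[~s.dropna().isin((0, 1))]
        if len(bad):
            audit.out_of_set[col] = bad.tolist()
            s = s.where(s.isin((0, 1)) | s.isna(), other=default)
        n_missing = int(s.isna().sum())
        if n_missing:
            mode = int(s.dropna().astype(int).mode().iloc[0])
            s = s.fillna(mode)
            audit.imputed[col] = n_missing
        df[col] = s.astype(int)
    return FeatureTable(df, dict(table.kinds)), audit


def fleiss_kappa(ratings: np.ndarray | pd.DataFrame) -> float:
    """Fleiss' kappa for items x raters categorical labels.

    Returns NaN (with a warning) when expected agreement is 1 — e.g. every
    rating is the same single category — where kappa is undefined.
    """
    arr = np.asarray(ratings)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need >= 2 items and >= 2 raters")
    counts, _ = aggregate_raters(arr)
    pj = counts.sum(axis=0) / counts.sum()
    if np.isclose((pj**2).sum(), 1.0):
        warnings.warn("expected agreement is 1; Fleiss' kappa undefined (NaN)")
        return float("nan")
    return float(_sm_fleiss(counts))


# --------------------------------------------------------------------------
# end-to-end extraction
# --------------------------------------------------------------------------


def extract_feature_table(samples, demographics: pd.DataFrame | None = None) -> FeatureTable:
    """Lab + GLCM features for a list of samples, plus optional demographics.

    ``demographics`` (indexed by sample id) may carry ``age`` (continuous)
    and ``sex`` (binary, 0 = male / 1 = female); columns are appended as-is.
    """
    rows = {}
    for s in samples:
        feats = lab_stats(s.image, s.mask).as_dict()
        feats.update(glcm_features(s.image, s.mask).as_dict())
        rows[s.sample_id or f"s{len(rows):04d}"] = feats
    df = pd.DataFrame.from_dict(rows, orient="index")
    kinds = {c: "continuous" for c in df.columns}
    if demographics is not None:
        df = df.join(demographics)
        for c in demographics.columns:
            kinds[c] = "binary" if c == "sex" else "continuous"
    if df.isna().any().any():
        raise ValueError("missing values after feature extraction")
    return FeatureTable(df, kinds)
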