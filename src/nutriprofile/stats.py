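"""Agreement statistics across nutrient profile models.

Approval proportions are reported both per food and per commercial (each food
weighted by how often its commercial was broadcast). Confidence intervals use
the normal-approximation binomial with n = number of *foods* for both point
estimates: repeated broadcasts of the same commercial carry no additional
sampling variance, so the food-level standard error also applies to the
commercial-weighted percentage.

Pairwise agreement between two models is Cohen's kappa on the weighted 2x2
contingency table, each food contributing its commercial count as a frequency
weight; kappa is interpreted on the conventional bands (fair / moderate /
good and their complements).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .data import CommercialDataset
from .errors import DataError

Z_95 = 1.959963984540054  # two-sided 95% normal quantile

KAPPA_BAND_STARS = {"fair": "*", "moderate": "**", "good": "***"}


@dataclass(frozen=True)
class ApprovalSummary:
    """One model's approval rates with 95% CIs (percentage scale)."""

    model_id: str
    n_foods_total: int
    n_commercials_total: int
    n_foods_approved: int
    pct_foods_approved: float
    foods_ci: tuple[float, float]
    pct_commercials_approved: float
    commercials_ci: tuple[float, float]


def binomial_halfwidth_pct(p: float, n: int, z: float = Z_95) -> float:
    """Normal-approximation binomial CI half-width, percentage scale.

    ``p`` is a fraction in [0, 1]; ``n`` the number of independent units
    (foods). Returns z * sqrt(p(1-p)/n) * 100.
    """
    if not 0 <= p <= 1:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if n < 1:
        raise ValueError("n must be >= 1")
    return z * math.sqrt(p * (1.0 - p) / n) * 100.0


def proportion_ci_pct(point_pct: float, halfwidth_pct: float) -> tuple[float, float]:
    """Symmetric CI around a percentage point estimate, clipped to [0, 100]."""
    lo = max(0.0, point_pct - halfwidth_pct)
    hi = min(100.0, point_pct + halfwidth_pct)
    return lo, hi


def _aligned_flags(
    approved: Mapping[str, bool], foods: CommercialDataset
) -> np.ndarray:
    missing = [f.id for f in foods if f.id not in approved]
    if missing:
        raise DataError(f"foods without a classification: {missing[:5]}")
    return np.array([bool(approved[f.id]) for f in foods])


def approval_summary(
    approved: Mapping[str, bool], foods: CommercialDataset, model_id: str = ""
) -> ApprovalSummary:
    """Food- and commercial-level approval percentages with 95% CIs.

    The same food-based standard error is applied to both point estimates
    (broadcast repetition adds no variance); both intervals are clipped to
    [0, 100].
    """
    if foods.n_foods == 0:
        raise DataError("approval summary needs at least one food")
    flags = _aligned_flags(approved, foods)
    weights = np.array([f.commercial_count for f in foods], dtype=float)
    n = foods.n_foods
    n_approved = int(flags.sum())
    pf = n_approved / n
    total_weight = weights.sum()
    if total_weight <= 0:
        raise DataError("dataset has zero total commercial weight")
    pc = float(weights[flags].sum() / total_weight)
    h = binomial_halfwidth_pct(pf, n)
    return ApprovalSummary(
        model_id=model_id,
        n_foods_total=n,
        n_commercials_total=foods.total_commercials,
        n_foods_approved=n_approved,
        pct_foods_approved=100.0 * pf,
        foods_ci=proportion_ci_pct(100.0 * pf, h),
        pct_commercials_approved=100.0 * pc,
        commercials_ci=proportion_ci_pct(100.0 * pc, h),
    )


def cohens_kappa(
    a: Sequence[bool],
    b: Sequence[bool],
    weights: Optional[Sequence[float]] = None,
) -> float:
    """Chance-corrected agreement between two binary classifications.

    Builds the weighted 2x2 contingency table (weights default to 1),
    computes the observed agreement fraction po and the chance agreement
    pe from the marginals, and returns (po - pe) / (1 - pe). Perfect
    agreement returns exactly 1; pe = 1 with po < 1 is undefined and
    returned as NaN.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise DataError("classifications must be equal-length 1-d sequences")
    if weights is None:
        w = np.ones(a.shape[0], dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != a.shape:
            raise DataError("weights must align with the classifications")
        if (w < 0).any():
            raise DataError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise DataError("total weight must be > 0")

    po = float(w[a == b].sum() / total)
    if po == 1.0:
        return 1.0
    pa1 = float(w[a].sum() / total)
    pb1 = float(w[b].sum() / total)
    pe = pa1 * pb1 + (1.0 - pa1) * (1.0 - pb1)
    if pe == 1.0:
        return math.nan
    return (po - pe) / (1.0 - pe)


def interpret_kappa(kappa: float) -> str:
    """Interpretation band for a kappa value in [-1, 1]."""
    if math.isnan(kappa):
        return "undefined"
    if not -1.0 <= kappa <= 1.0 + 1e-12:
        raise ValueError(f"kappa must be in [-1, 1], got {kappa}")
    # Boundary ownership follows the printed ranges: 0.40 is "fair",
    # 0.60 "moderate", 0.80 "good"; 0.21 is the lower edge of "fair".
    if kappa > 0.80:
        return "very good"
    if kappa > 0.60:
        return "good"
    if kappa > 0.40:
        return "moderate"
    if kappa >= 0.21:
        return "fair"
    return "less than fair"


@dataclass(frozen=True)
class AgreementMatrix:
    """Pairwise kappa matrix over models, with interpretation bands."""

    model_ids: tuple[str, ...]
    kappa: pd.DataFrame
    bands: pd.DataFrame
    weight_note: str = "weighted by number of commercials"

    def starred(self) -> pd.DataFrame:
        """Upper-triangular display form: kappa to 2 dp plus band stars."""
        out = pd.DataFrame(
            "", index=self.kappa.index, columns=self.kappa.columns
        )
        for i, row in enumerate(self.model_ids):
            for j, col in enumerate(self.model_ids):
                if j <= i:
                    continue
                k = self.kappa.loc[row, col]
                stars = KAPPA_BAND_STARS.get(self.bands.loc[row, col], "")
                out.loc[row, col] = f"{k:.2f}{stars}" if not math.isnan(k) else "NA"
        return out


def agreement_matrix(
    flags_by_model: Mapping[str, Mapping[str, bool]],
    foods: CommercialDataset,
) -> AgreementMatrix:
    """All pairwise commercial-weighted kappas between models."""
    model_ids = tuple(flags_by_model)
    if not model_ids:
        raise DataError("agreement matrix needs at least one model")
    weights = np.array([f.commercial_count for f in foods], dtype=float)
    arrays = {
        m: _aligned_flags(flags_by_model[m], foods) for m in model_ids
    }
    kappa = pd.DataFrame(np.eye(len(model_ids)), index=model_ids, columns=model_ids)
    bands = pd.DataFrame("", index=model_ids, columns=model_ids)
    for i, mi in enumerate(model_ids):
        bands.loc[mi, mi] = interpret_kappa(1.0)
        for mj in model_ids[i + 1 :]:
            k = cohens_kappa(arrays[mi], arrays[mj], weights)
            kappa.loc[mi, mj] = kappa.loc[mj, mi] = k
            band = interpret_kappa(k)
            bands.loc[mi, mj] = bands.loc[mj, mi] = band
    return AgreementMatrix(model_ids=model_ids, kappa=kappa, bands=bands)


@dataclass(frozen=True)
class CategoryBreakdown:
    """Percentage of commercials approved per food-guide category and model.

    ``table`` rows are reporting categories (the fatty/sugary group split
    into snacks, not-snacks and drinks), columns are models; NaN marks a
    category with zero commercial weight, where the percentage is undefined.
    """

    table: pd.DataFrame
    category_weights: pd.Series


def category_breakdown(
    flags_by_model: Mapping[str, Mapping[str, bool]],
    foods: CommercialDataset,
    split_fatty_sugary: bool = True,
) -> CategoryBreakdown:
    """Commercial-weighted approval percentage per category and model."""
    records = []
    for food in foods:
        category = (
            food.reporting_category if split_fatty_sugary else food.food_guide_category
        )
        records.append((food.id, category, food.commercial_count))
    frame = pd.DataFrame(records, columns=["id", "category", "weight"])
    categories = sorted(frame["category"].unique())
    table = pd.DataFrame(index=categories, columns=list(flags_by_model), dtype=float)
    for model_id, approved in flags_by_model.items():
        flags = _aligned_flags(approved, foods)
        frame[model_id] = flags
    weights_by_cat = frame.groupby("category")["weight"].sum()
    for category in categories:
        sub = frame[frame["category"] == category]
        total = sub["weight"].sum()
        for model_id in flags_by_model:
            if total == 0:
                table.loc[category, model_id] = math.nan
            else:
                approved_weight = sub.loc[sub[model_id], "weight"].sum()
                table.loc[category, model_id] = 100.0 * approved_weight / total
    return CategoryBreakdown(table=table, category_weights=weights_by_cat)


@dataclass(frozen=True)
class ApprovingModelCounts:
    """Per-food count of approving models plus its weighted distribution."""

    counts: pd.Series  # index: food id, value: int in [0, n_models]
    n_models: int
    distribution: pd.Series  # commercial-weighted share (%) per count value
    pct_commercials_approved_by_none: float
    pct_commercials_approved_by_all: float


def approving_model_count(
    flags_by_model: Mapping[str, Mapping[str, bool]],
    foods: CommercialDataset,
) -> ApprovingModelCounts:
    """How many models approve each food, and the weighted shares at 0/all."""
    if not flags_by_model:
        raise DataError("approving_model_count needs at least one model")
    arrays = {m: _aligned_flags(f, foods) for m, f in flags_by_model.items()}
    n_models = len(arrays)
    stacked = np.vstack(list(arrays.values()))
    counts = stacked.sum(axis=0)
    weights = np.array([f.commercial_count for f in foods], dtype=float)
    total = weights.sum()
    if total <= 0:
        raise DataError("dataset has zero total commercial weight")
    index = pd.Index([f.id for f in foods], name="food_id")
    dist = pd.Series(
        {
            c: 100.0 * weights[counts == c].sum() / total
            for c in range(n_models + 1)
        },
        name="pct_commercials",
    )
    return ApprovingModelCounts(
        counts=pd.Series(counts, index=index, name="n_models_approving"),
        n_models=n_models,
        distribution=dist,
        pct_commercials_approved_by_none=float(dist.loc[0]),
        pct_commercials_approved_by_all=float(dist.loc[n_models]),
    )
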