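"""Marker-validation ANOVA and metabolite group-contrast arithmetic.

Two small downstream analyses accompany the genome scans: (i) validation of
a co-dominant marker in backcross families by a two-way ANOVA of trait
value on marker dosage (donor-allele copies, entered first) and family,
with sequential (type-I) variance decomposition, an additive allele-effect
estimate and residual-based recombinant detection; (ii) a group contrast of
metabolite feature areas between marker classes — arithmetic group means,
their ratio, the log2 fold change and a Welch t-test on log areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.outliers_influence import OLSInfluence

__all__ = [
    "AnovaResult",
    "two_way_anova",
    "detect_recombinants",
    "MetabContrast",
    "metab_contrast",
    "metab_table",
    "round_half_away",
]

_REQUIRED = ("individual", "dosage", "family", "trait")


@dataclass
class AnovaResult:
    """Sequential (type-I) two-way ANOVA decomposition.

    ``terms`` holds one row per term (dosage, family, residual) with
    sum_sq, df, percent_variance, F and p; ``effect`` is the fitted trait
    change per donor-allele copy.  ``degenerate`` flags a zero-variance
    trait (percentages undefined).
    """

    terms: pd.DataFrame
    effect: float
    degenerate: bool = False
    model: object = field(default=None, repr=False)

    def percent(self, term: str) -> float:
        return float(self.terms.loc[term, "percent_variance"])


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED if c not in table.columns]
    if missing:
        raise ValueError(f"marker table lacks columns {missing}")
    t = table.copy()
    if not set(np.unique(t["dosage"])) <= {0, 1, 2}:
        raise ValueError("dosage must take values in {0, 1, 2}")
    if t["family"].nunique() < 2:
        raise ValueError("need at least two families for the two-way model")
    if not np.isfinite(t["trait"].to_numpy(dtype=float)).all():
        raise ValueError("trait values must be finite")
    if t.groupby("family")["trait"].count().min() == 0:
        raise ValueError("empty family")
    return t


def two_way_anova(table: pd.DataFrame, dosage_first: bool = True) -> AnovaResult:
    """Fit ``trait ~ dosage + C(family)`` and decompose variance sequentially.

    Dosage enters as a numeric covariate (additive per donor allele) first
    by default, so its share of the total sum of squares is reported before
    family; ``dosage_first=False`` reverses the entry order.  Percent
    variance is SS_term / SS_total x 100 over dosage, family and residual.
    Raises on a confounded design (dosage constant within every family).
    """
    t = _validate_table(table)
    if (t.groupby("family")["dosage"].nunique() == 1).all():
        raise ValueError(
            "confounded design: marker dosage is constant within every family, "
            "so dosage and family effects cannot be separated"
        )
    trait = t["trait"].to_numpy(dtype=float)
    if np.allclose(trait, trait[0]):
        terms = pd.DataFrame(
            {
                "sum_sq": [0.0, 0.0, 0.0],
                "df": [1.0, float(t["family"].nunique() - 1), float(len(t) - t["family"].nunique() - 1)],
                "percent_variance": [np.nan] * 3,
                "F": [np.nan] * 3,
                "p": [np.nan] * 3,
            },
            index=["dosage", "family", "residual"],
        )
        return AnovaResult(terms=terms, effect=0.0, degenerate=True)

    # sequential SS from nested fits: patsy fixes its own term order inside
    # one formula, so the entry order is imposed explicitly here
    full = smf.ols("trait ~ dosage + C(family)", data=t).fit()
    null_fit = smf.ols("trait ~ 1", data=t).fit()
    first_term = "dosage" if dosage_first else "C(family)"
    mid = smf.ols(f"trait ~ {first_term}", data=t).fit()
    ss_first = float(null_fit.ssr - mid.ssr)
    ss_second = float(mid.ssr - full.ssr)
    ss_resid = float(full.ssr)
    ss_dosage, ss_family = (
        (ss_first, ss_second) if dosage_first else (ss_second, ss_first)
    )
    n = len(t)
    df_dosage = 1.0
    df_family = float(t["family"].nunique() - 1)
    df_resid = float(n - 1 - df_dosage - df_family)
    ms_resid = ss_resid / df_resid
    f_dosage = ss_dosage / df_dosage / ms_resid
    f_family = ss_family / df_family / ms_resid
    ss_total = ss_dosage + ss_family + ss_resid
    terms = pd.DataFrame(
        {
            "sum_sq": [ss_dosage, ss_family, ss_resid],
            "df": [df_dosage, df_family, df_resid],
            "percent_variance": [
                100.0 * ss_dosage / ss_total,
                100.0 * ss_family / ss_total,
                100.0 * ss_resid / ss_total,
            ],
            "F": [f_dosage, f_family, np.nan],
            "p": [
                float(stats.f.sf(f_dosage, df_dosage, df_resid)),
                float(stats.f.sf(f_family, df_family, df_resid)),
                np.nan,
            ],
        },
        index=["dosage", "family", "residual"],
    )
    return AnovaResult(terms=terms, effect=float(full.params["dosage"]), model=full)


def detect_recombinants(
    table: pd.DataFrame, fitted: AnovaResult, z_cut: float = 2.5
) -> list:
    """Flag putative recombinants (marker genotype contradicting phenotype).

    An individual is flagged when its externally studentised residual
    exceeds ``z_cut`` in magnitude AND its trait value falls inside the
    observed trait range of some other dosage class — i.e. it looks like a
    member of the opposite marker class rather than a mere outlier.
    """
    t = _validate_table(table)
    if fitted.degenerate or fitted.model is None:
        return []
    if not np.isfinite(z_cut):
        return []
    resid = OLSInfluence(fitted.model).resid_studentized_external
    ranges = {
        d: (grp["trait"].min(), grp["trait"].max())
        for d, grp in t.groupby("dosage")
    }
    flagged = []
    for i, row in enumerate(t.itertuples(index=False)):
        if abs(resid[i]) <= z_cut:
            continue
        for d, (lo, hi) in ranges.items():
            if d != row.dosage and lo <= row.trait <= hi:
                flagged.append(row.individual)
                break
    return flagged


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round with halves away from zero (printed-table convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).copy_abs().quantize(q, rounding=ROUND_HALF_UP)
                 * (1 if x >= 0 else -1))


@dataclass
class MetabContrast:
    """Group contrast of one feature's areas between marker classes."""

    mean_plus: float
    mean_minus: float
    ratio: float
    log2fold: float
    p: float

    def printed(self, ndigits: int = 2) -> tuple[float, float]:
        """(ratio, log2fold) rounded as printed in summary tables."""
        return (
            round_half_away(self.ratio, ndigits),
            round_half_away(self.log2fold, ndigits),
        )


def metab_contrast(
    areas_plus: np.ndarray | pd.Series,
    areas_minus: np.ndarray | pd.Series,
) -> MetabContrast:
    """Group means, +/- ratio, log2 fold change and Welch-t p-value.

    The ratio is computed from the arithmetic group means of the raw areas
    (not the mean of per-sample ratios); the two-sided p-value is a Welch
    t-test on log-transformed areas.  Antisymmetric in log2fold under group
    exchange.
    """
    plus = np.asarray(areas_plus, dtype=float)
    minus = np.asarray(areas_minus, dtype=float)
    if plus.size == 0 or minus.size == 0:
        raise ValueError("both groups must be non-empty")
    if (plus <= 0).any() or (minus <= 0).any():
        raise ValueError("areas must be positive")
    mean_plus = float(plus.mean())
    mean_minus = float(minus.mean())
    ratio = mean_plus / mean_minus
    if plus.size > 1 and minus.size > 1:
        p = float(
            stats.ttest_ind(np.log(plus), np.log(minus), equal_var=False).pvalue
        )
    else:
        p = float("nan")
    return MetabContrast(
        mean_plus=mean_plus,
        mean_minus=mean_minus,
        ratio=ratio,
        log2fold=float(np.log2(ratio)),
        p=p,
    )


def metab_table(
    features: pd.DataFrame, groups: pd.Series | dict
) -> pd.DataFrame:
    """Apply :func:`metab_contrast` to every row of a feature x sample matrix.

    ``groups`` maps sample (column) names to 'plus'/'minus'.  Returns a tidy
    frame with one row per feature: group means, ratio, log2fold, p.
    """
    groups = pd.Series(groups)
    plus_cols = groups[groups == "plus"].index
    minus_cols = groups[groups == "minus"].index
    if len(plus_cols) == 0 or len(minus_cols) == 0:
        raise ValueError("groups must contain both 'plus' and 'minus' samples")
    rows = []
    for feat, row in features.iterrows():
        c = metab_contrast(row[plus_cols], row[minus_cols])
        rows.append(
            {
                "feature": feat,
                "group_area_plus": c.mean_plus,
                "group_area_minus": c.mean_minus,
                "ratio": c.ratio,
                "log2fold": c.log2fold,
                "p": c.p,
            }
        )
    return pd.DataFrame(rows).set_index("feature")
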