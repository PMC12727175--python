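"""Inter-/intra-rater agreement and correlation statistics.

Implements the statistics used to compare symmetry assessments: weighted
Cohen's kappa between raters' binary (or ordinal three-level) scores,
Spearman's rank correlation between quantitative parameters, interpretation
band tables for both, and the all-pairs Spearman correlation matrix.

Two kappa interpretation schemes ship: the Landis–Koch-style bands
(default; 0–0.20 slight, 0.21–0.40 fair, 0.41–0.60 moderate, 0.61–0.80
substantial, 0.81–1.00 almost perfect) and the McHugh bands.  Rho bands
follow Schober's guidance and are applied to |rho|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import cohen_kappa_score

SCORE_COLUMNS = ["subject", "rater", "plane", "movement", "score", "lagging"]

# Ordered encoding for the three-level score used with linear weighting.
THREE_LEVEL_ORDER = {"lag-left": 0, "none": 1, "lag-right": 2}


@dataclass(frozen=True)
class BandTable:
    """Ordered (lower bound, label) interpretation bands over (-1, 1]."""

    scheme: str
    bands: tuple[tuple[float, str], ...]

    def __post_init__(self) -> None:
        lowers = [b[0] for b in self.bands]
        if lowers != sorted(lowers) or len(set(lowers)) != len(lowers):
            raise ValueError("band lower bounds must be strictly increasing")
        if lowers[0] > -1.0:
            raise ValueError("bands must cover (-1, 1]")

    def label(self, statistic: float) -> str:
        chosen = self.bands[0][1]
        for lower, lab in self.bands:
            if statistic >= lower:
                chosen = lab
        return chosen


KAPPA_BANDS = {
    "landis": BandTable(
        "landis",
        (
            (-1.0, "poor"),
            (0.0, "slight"),
            (0.21, "fair"),
            (0.41, "moderate"),
            (0.61, "substantial"),
            (0.81, "almost perfect"),
        ),
    ),
    "mchugh": BandTable(
        "mchugh",
        (
            (-1.0, "none"),
            (0.21, "minimal"),
            (0.40, "weak"),
            (0.60, "moderate"),
            (0.80, "strong"),
            (0.90, "almost perfect"),
        ),
    ),
}

RHO_BANDS = {
    "schober": BandTable(
        "schober",
        (
            (-1.0, "negligible"),
            (0.10, "weak"),
            (0.40, "moderate"),
            (0.70, "strong"),
            (0.90, "very strong"),
        ),
    ),
}

DEFAULT_KAPPA_SCHEME = "landis"
DEFAULT_RHO_SCHEME = "schober"


@dataclass(frozen=True)
class AgreementStat:
    """A kappa or rho value with its interpretation label."""

    statistic: float
    label: str
    n: int
    kind: str  # "kappa" | "rho"

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.statistic <= 1.0 + 1e-12:
            raise ValueError("statistic must lie in [-1, 1]")
        if self.n < 1:
            raise ValueError("n must be positive")
        if self.kind not in ("kappa", "rho"):
            raise ValueError("kind must be 'kappa' or 'rho'")


def interpret(statistic: float, bands: BandTable, use_abs: bool = False) -> str:
    """Label of the highest band whose lower bound <= statistic."""
    if not -1.0 <= statistic <= 1.0:
        raise ValueError("statistic must lie in [-1, 1]")
    return bands.label(abs(statistic) if use_abs else statistic)


def cohen_kappa(
    ratings_a,
    ratings_b,
    weighting: str = "unweighted",
    bands: BandTable | None = None,
) -> AgreementStat:
    """Weighted Cohen's kappa between two raters' categorical sequences.

    For binary data the unweighted, linear and quadratic weightings
    coincide.  When both raters use a single common category (zero expected
    disagreement) kappa is undefined; perfect observed agreement is
    reported as 1.0, anything else is an error.
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("ratings must be equal-length 1-D sequences")
    if len(a) < 2:
        raise ValueError("need at least 2 ratings")
    weights = {"unweighted": None, "linear": "linear", "quadratic": "quadratic"}
    if weighting not in weights:
        raise ValueError(f"weighting must be one of {sorted(weights)}")
    if bands is None:
        bands = KAPPA_BANDS[DEFAULT_KAPPA_SCHEME]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate-marginal chatter
        kappa = cohen_kappa_score(a, b, weights=weights[weighting])
    if np.isnan(kappa):
        if np.all(a == b):
            kappa = 1.0
        else:
            raise ValueError("degenerate marginals: kappa undefined")
    kappa = float(kappa)
    return AgreementStat(
        statistic=kappa, label=interpret(kappa, bands), n=len(a), kind="kappa"
    )


def spearman_rho(x, y, bands: BandTable | None = None) -> AgreementStat:
    """Spearman rank correlation (mid-ranks for ties), labelled on |rho|."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D sequences")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if bands is None:
        bands = RHO_BANDS[DEFAULT_RHO_SCHEME]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(x, y).statistic
    if np.isnan(rho):
        raise ValueError("constant input: rank correlation undefined")
    rho = float(rho)
    return AgreementStat(
        statistic=rho,
        label=interpret(rho, bands, use_abs=True),
        n=len(x),
        kind="rho",
    )


def correlation_matrix(
    table: pd.DataFrame, min_complete: int = 3
) -> pd.DataFrame:
    """Pairwise-complete Spearman correlation matrix of named parameters.

    Rows are subjects, columns named parameters.  Cells with fewer than
    ``min_complete`` complete pairs are NaN (flagged missing, not an
    error); the diagonal is 1.
    """
    if table.shape[1] < 1:
        raise ValueError("need at least one parameter column")
    corr = table.corr(method="spearman", min_periods=min_complete)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def validate_score_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check an expert score table (long format) for structural validity."""
    missing = [c for c in SCORE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"score table missing columns: {missing}")
    if not table["score"].isin([0, 1]).all():
        raise ValueError("scores must be 0 or 1")
    if not table["lagging"].isin(["none", "right", "left"]).all():
        raise ValueError("lagging must be 'none', 'right' or 'left'")
    bad = table[(table["score"] == 0) & (table["lagging"] != "none")]
    if len(bad):
        raise ValueError("score 0 rows must have lagging 'none'")
    return table[SCORE_COLUMNS]


def three_level_encoding(score, lagging) -> np.ndarray:
    """Encode (score, lagging) pairs on the ordered scale lag-left < none < lag-right."""
    score = np.asarray(score)
    lagging = np.asarray(lagging)
    out = np.full(score.shape, THREE_LEVEL_ORDER["none"], dtype=int)
    out[(score == 1) & (lagging == "left")] = THREE_LEVEL_ORDER["lag-left"]
    out[(score == 1) & (lagging == "right")] = THREE_LEVEL_ORDER["lag-right"]
    return out


def mean_expert_score(scores_a, scores_b) -> np.ndarray:
    """Mean of two binary scores, with 0.5 ties resolved toward 1.

    Averaging two raters' binary scores can yield 0.5; the asymmetric
    reading (score 1) is retained so borderline cases stay flagged.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    return (0.5 * (a + b) >= 0.5 - 1e-12).astype(int)
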