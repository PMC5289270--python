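"""Rate curves, extrapolation arithmetic, and the statistical tests.

The extrapolation logic: the precedent rate of *interacting* pairs
measures the completeness of the template library (if the library were
complete, every interacting pair would have a precedent), so the observed
precedent rate of non-interacting pairs divided by the positive rate is
the completeness-corrected estimate of how many non-interacting pairs
have compatible structures.  The expected precedent rate under pure
false-negative contamination is the positive rate times the interactome
density; the ratio of the observed negative rate to that expectation is
the enrichment factor.

Standard tests are delegated to scipy/statsmodels; the Cramer two-sample
test (Baringhaus-Franz statistic with a permutation bootstrap) has no
installed implementation and is provided here, vectorized over
permutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "RateCurve",
    "ExtrapolationResult",
    "precedent_rate_curve",
    "network_density",
    "expected_contamination",
    "enrichment_factor",
    "completeness_corrected_rate",
    "extrapolate",
    "fisher_exact_2x2",
    "cramer_two_sample",
    "hypergeom_enrichment",
    "round_percent",
]


@dataclass
class RateCurve:
    """Precedent detection rate as a function of the TMmin threshold."""

    thresholds: np.ndarray
    rates: np.ndarray
    n_pairs: int

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(np.diff(self.thresholds) < 0):
            raise ValueError("thresholds must be ascending")
        if np.any(np.diff(self.rates) > 1e-12):
            raise ValueError("rates must be non-increasing in threshold")

    def rate_at(self, threshold: float) -> float:
        i = int(np.argmin(np.abs(self.thresholds - threshold)))
        return float(self.rates[i])


def precedent_rate_curve(
    tmmins: list[float | None], thresholds
) -> RateCurve:
    """Fraction of pairs (with models) whose best valid TMmin reaches t.

    ``tmmins`` holds, per pair with 3D models, the best valid-interface
    TMmin or None when no valid precedent was found at any threshold.
    """
    thresholds = np.asarray(sorted(thresholds), dtype=float)
    n = len(tmmins)
    if n == 0:
        raise ValueError("no pairs")
    vals = np.array([v if v is not None else -1.0 for v in tmmins])
    rates = np.array([(vals >= t).mean() for t in thresholds])
    return RateCurve(thresholds=thresholds, rates=rates, n_pairs=n)


def network_density(n_interactions: int, n_proteins: int) -> float:
    """Observed interactions as a percentage of all possible pairs."""
    if n_proteins < 2:
        raise ValueError("need at least 2 proteins")
    possible = n_proteins * (n_proteins - 1) // 2
    if n_interactions > possible:
        raise ValueError("more interactions than possible pairs")
    return 100.0 * n_interactions / possible


def expected_contamination(positive_rate: float, density: float) -> float:
    """Precedent rate (%) expected from random false-negative contamination."""
    if positive_rate < 0 or density < 0:
        raise ValueError("rates must be non-negative")
    return positive_rate * density / 100.0


def enrichment_factor(observed_rate: float, expected_rate: float) -> float:
    """How many times the observed rate exceeds the chance expectation."""
    if expected_rate <= 0:
        raise ValueError("expected rate must be positive")
    return observed_rate / expected_rate


def completeness_corrected_rate(negative_rate: float, positive_rate: float) -> float:
    """Negative precedent rate (%) corrected for library completeness.

    Uses the positive rate as a proxy of library completeness:
    100 * negative_rate / positive_rate.
    """
    if positive_rate <= 0:
        raise ValueError("positive rate must be positive")
    return 100.0 * negative_rate / positive_rate


@dataclass
class ExtrapolationResult:
    """The full extrapolation bundle, all rates in percent."""

    negative_rate: float
    positive_rate: float
    density: float
    expected_contamination: float
    enrichment_factor: float
    completeness_corrected_rate: float


def extrapolate(
    negative_rate: float, positive_rate: float, density: float
) -> ExtrapolationResult:
    """Assemble the extrapolation quantities from the three input rates."""
    exp = expected_contamination(positive_rate, density)
    return ExtrapolationResult(
        negative_rate=negative_rate,
        positive_rate=positive_rate,
        density=density,
        expected_contamination=exp,
        enrichment_factor=enrichment_factor(negative_rate, exp),
        completeness_corrected_rate=completeness_corrected_rate(
            negative_rate, positive_rate
        ),
    )


def round_percent(value: float, decimals: int = 1) -> float:
    """Round a percentage the way the tables print them."""
    return float(np.round(value, decimals))


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Two-sided by the probability-mass rule: sum of hypergeometric
    probabilities of all tables (at fixed margins) no more probable than
    the observed one.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t < 0) or np.any(t != np.floor(t)):
            raise ValueError("counts must be non-negative integers")
        t = t.astype(int)
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def _cramer_statistic_from_matrix(phi: np.ndarray, is_x: np.ndarray) -> np.ndarray:
    """Baringhaus-Franz T for one or many group labellings.

    ``phi`` is the pooled N x N matrix of phi(z_i - z_j); ``is_x`` is a
    (B, N) 0/1 matrix marking the first sample.  Returns B statistics.
    """
    A = np.atleast_2d(is_x).astype(float)
    N = phi.shape[0]
    m = A.sum(axis=1)
    n = N - m
    r = phi.sum(axis=1)
    M = A @ phi
    sxx = (M * A).sum(axis=1)
    sx_all = A @ r
    sxy = sx_all - sxx
    s_tot = phi.sum()
    syy = s_tot - 2 * sx_all + sxx
    T = (m * n / (m + n)) * (
        2.0 * sxy / (m * n) - sxx / m**2 - syy / n**2
    )
    return T


def cramer_two_sample(
    x,
    y,
    n_boot: int = 1000,
    seed: int | None = None,
    method: str = "permutation",
):
    """Cramer two-sample test (Baringhaus-Franz), p by resampling.

    T = mn/(m+n) * [ 2/(mn) sum phi(x_i - y_j) - 1/m^2 sum phi(x_i - x_j)
    - 1/n^2 sum phi(y_i - y_j) ] with phi(z) = |z|/2.  The p-value
    resamples the pooled observations: label permutation by default, or an
    ordinary bootstrap with ``method="bootstrap"``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    N = m + n
    phi = np.abs(pooled[:, None] - pooled[None, :]) / 2.0
    base = np.zeros(N)
    base[:m] = 1.0
    T_obs = float(_cramer_statistic_from_matrix(phi, base)[0])
    if N < 3 or n_boot <= 0:
        return T_obs, float("nan")
    rng = np.random.default_rng(seed)
    if method == "permutation":
        A = np.zeros((n_boot, N))
        for b in range(n_boot):
            idx = rng.permutation(N)[:m]
            A[b, idx] = 1.0
        T_null = _cramer_statistic_from_matrix(phi, A)
    elif method == "bootstrap":
        T_null = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, N, size=N)
            zb = pooled[idx]
            phib = np.abs(zb[:, None] - zb[None, :]) / 2.0
            T_null[b] = _cramer_statistic_from_matrix(phib, base)[0]
    else:
        raise ValueError(f"unknown method {method!r}")
    p = (1.0 + np.sum(T_null >= T_obs)) / (1.0 + n_boot)
    return T_obs, float(p)


def hypergeom_enrichment(
    study_set,
    term_map: dict[str, set[str]],
    universe,
    alpha: float = 0.05,
    return_all: bool = False,
) -> pd.DataFrame:
    """Term over-representation: upper-tail hypergeometric + BH correction.

    ``term_map`` maps each term to the universe proteins carrying it.
    Terms with no annotated universe member are skipped with a warning.
    Returns the terms with adjusted p <= alpha (or all terms with
    ``return_all``).
    """
    study = set(study_set)
    uni = set(universe)
    if not study <= uni:
        raise ValueError("study set must be a subset of the universe")
    N, n = len(uni), len(study)
    rows = []
    for term, annotated in sorted(term_map.items()):
        K = len(annotated & uni)
        if K == 0:
            logger.warning("term %s annotates nothing in the universe; skipped", term)
            continue
        k = len(annotated & study)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k_study": k, "k_universe": K, "p": p})
    df = pd.DataFrame(rows)
    if df.empty:
        df["p_adj"] = []
        df["significant"] = []
        return df
    _, p_adj, _, _ = multipletests(df["p"].to_numpy(), method="fdr_bh")
    df["p_adj"] = p_adj
    df["significant"] = df["p_adj"] <= alpha
    if return_all:
        return df
    return df[df["significant"]].reset_index(drop=True)
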