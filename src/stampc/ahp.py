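"""Analytic Hierarchy Process core.

Criterion weights are derived from a positive reciprocal pairwise-comparison
matrix (judgments on Saaty's 1-9 scale).  The default extraction is the
principal right eigenvector, computed by power iteration; row geometric
means are available as a cross-check — both agree exactly for perfectly
consistent matrices.

Consistency diagnostics follow the classic definitions:
``CI = (lambda_max - n) / (n - 1)`` and ``CR = CI / RI(n)`` with Saaty's
random-index table; CR below 0.10 is deemed acceptable internal coherence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import ValidationReport

# Saaty's random consistency index by matrix order.
RANDOM_INDEX = {
    1: 0.00,
    2: 0.00,
    3: 0.58,
    4: 0.90,
    5: 1.12,
    6: 1.24,
    7: 1.32,
    8: 1.41,
    9: 1.45,
    10: 1.49,
}

CR_ACCEPTABLE_THRESHOLD = 0.10


class AHPError(ValueError):
    pass


@dataclass(frozen=True)
class AHPResult:
    weights: np.ndarray
    lambda_max: float
    consistency_index: float
    consistency_ratio: float
    method: str

    @property
    def acceptable(self) -> bool:
        return self.consistency_ratio < CR_ACCEPTABLE_THRESHOLD


def _as_matrix(matrix) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise AHPError(f"pairwise matrix must be square, got shape {m.shape}")
    if not np.all(np.isfinite(m)) or np.any(m <= 0):
        raise AHPError("pairwise matrix entries must be positive finite reals")
    return m


def validate_pairwise_matrix(matrix, strict_saaty: bool = True) -> ValidationReport:
    """List structural violations: diagonal, reciprocity, Saaty scale bounds.

    With ``strict_saaty`` off, out-of-scale entries are reported as warnings
    (prefixed) rather than violations.
    """
    m = _as_matrix(matrix)
    n = m.shape[0]
    report = ValidationReport()
    for i in range(n):
        if abs(m[i, i] - 1.0) > 1e-9:
            report.add(f"diagonal entry [{i},{i}] = {m[i, i]} != 1")
    for i in range(n):
        for j in range(i + 1, n):
            if abs(m[j, i] - 1.0 / m[i, j]) > 1e-9:
                report.add(
                    f"reciprocity violated at [{i},{j}]: "
                    f"{m[i, j]} vs {m[j, i]}"
                )
    out_of_scale = [
        (i, j)
        for i in range(n)
        for j in range(n)
        if not (1.0 / 9 - 1e-12 <= m[i, j] <= 9 + 1e-12)
    ]
    for i, j in out_of_scale:
        msg = f"entry [{i},{j}] = {m[i, j]} outside Saaty scale [1/9, 9]"
        if strict_saaty:
            report.add(msg)
        else:
            report.warn(msg)
    return report


def _require_valid(matrix) -> np.ndarray:
    m = _as_matrix(matrix)
    report = validate_pairwise_matrix(m, strict_saaty=False)
    if not report.ok:
        raise AHPError("; ".join(report.violations))
    return m


def priority_weights(
    matrix, method: str = "eigenvector", max_iter: int = 10_000, tol: float = 1e-12
) -> np.ndarray:
    """Criterion weights, normalized to sum 1.

    ``eigenvector``: principal right eigenvector by power iteration,
    converged when successive normalized iterates differ by < tol in max
    norm.  ``geometric_mean``: row geometric means, normalized.
    """
    m = _require_valid(matrix)
    n = m.shape[0]
    if method == "geometric_mean":
        gm = np.exp(np.log(m).mean(axis=1))
        return gm / gm.sum()
    if method != "eigenvector":
        raise AHPError(f"unknown method {method!r}")
    w = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        w_new = m @ w
        w_new /= w_new.sum()
        if np.max(np.abs(w_new - w)) < tol:
            return w_new
        w = w_new
    raise AHPError(f"power iteration did not converge in {max_iter} iterations")


def consistency_ratio(matrix, method: str = "eigenvector") -> AHPResult:
    """Full AHP result: weights, lambda_max, CI, CR.

    lambda_max is the mean of the component-wise Rayleigh ratios
    ``(M w)_i / w_i`` — exact when w is the true principal eigenvector.
    CR is defined as 0 for n <= 2 (a reciprocal 2x2 is always consistent).
    """
    m = _require_valid(matrix)
    n = m.shape[0]
    if n > max(RANDOM_INDEX):
        raise AHPError(
            f"matrix order {n} exceeds the random-index table "
            f"(n <= {max(RANDOM_INDEX)})"
        )
    w = priority_weights(m, method=method)
    lambda_max = float(np.mean((m @ w) / w))
    if n <= 2:
        ci = 0.0
        cr = 0.0
    else:
        ci = (lambda_max - n) / (n - 1)
        cr = ci / RANDOM_INDEX[n]
    return AHPResult(
        weights=w,
        lambda_max=lambda_max,
        consistency_index=ci,
        consistency_ratio=cr,
        method=method,
    )


def consistent_matrix(weights) -> np.ndarray:
    """The perfectly consistent matrix generated by a weight vector
    (entries w_i / w_j); useful for constructing test cases."""
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise AHPError("weights must be positive")
    return np.outer(w, 1.0 / w)
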