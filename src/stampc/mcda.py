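"""Multi-criteria prioritization of the CT parameters.

Three evidence sources score each parameter: a systematic-review citation
frequency, an expert-audit consensus rank, and the surgeon-survey mean
rating.  Each source column is normalized, the columns are combined as a
weighted sum (weights from the AHP stage), and the final scores are ranked
and cut into tiers — Tier 1 "Essential" (score >= t1), Tier 2 "Highly
Recommended" (t2 <= score < t1), Tier 3 "Recommended" (score < t2).  The
Tier-1 set is the STAMP-C essential panel.

A Dirichlet weight-perturbation sensitivity analysis reports how stable the
top tier and the full ranking are under variation of the criterion weights.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from . import reference
from .catalog import PARAMETER_IDS, get_parameter

TIER_RECOMMENDATION = {1: "Essential", 2: "Highly Recommended", 3: "Recommended"}


class MCDAError(ValueError):
    pass


@dataclass(frozen=True)
class MCDAConfig:
    weights: tuple[float, ...] = reference.AHP_WEIGHTS
    criteria: tuple[str, ...] = reference.AHP_CRITERIA
    normalization: str = "sum_to_100"  # sum_to_100 | min_max | z_score
    scale_factor: float = 1.0
    tier_thresholds: tuple[float, float] = (9.0, 6.0)  # (t1, t2)

    def validate(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if len(w) != len(self.criteria):
            raise MCDAError("one weight per criterion required")
        if np.any(w <= 0):
            raise MCDAError("weights must be strictly positive")
        if abs(w.sum() - 1.0) > 1e-9:
            raise MCDAError(f"weights must sum to 1, got {w.sum()}")
        if self.scale_factor <= 0:
            raise MCDAError("scale_factor must be positive")
        t1, t2 = self.tier_thresholds
        if not t1 > t2:
            raise MCDAError("tier thresholds require t1 > t2")
        if self.normalization not in ("sum_to_100", "min_max", "z_score"):
            raise MCDAError(f"unknown normalization {self.normalization!r}")


def normalize_source(raw: pd.Series | np.ndarray, scheme: str) -> np.ndarray:
    """Normalize one source column.

    sum_to_100: scale so the column sums to 100.  min_max: affine map onto
    [0, 1].  z_score: mean 0, sample SD 1.  The latter two reject constant
    columns (degenerate).
    """
    x = np.asarray(raw, dtype=float)
    if x.size < 2:
        raise MCDAError("need at least 2 parameters to normalize")
    if scheme == "sum_to_100":
        total = x.sum()
        if total == 0:
            raise MCDAError("sum_to_100 undefined for an all-zero column")
        return 100.0 * x / total
    if scheme == "min_max":
        lo, hi = x.min(), x.max()
        if hi == lo:
            raise MCDAError("min_max undefined for a constant column")
        return (x - lo) / (hi - lo)
    if scheme == "z_score":
        sd = x.std(ddof=1)
        if sd == 0:
            raise MCDAError("z_score undefined for a constant column")
        return (x - x.mean()) / sd
    raise MCDAError(f"unknown normalization scheme {scheme!r}")


def aggregate(sources: pd.DataFrame, config: MCDAConfig) -> pd.Series:
    """Weighted sum of normalized source columns -> final score per parameter.

    ``sources`` must hold one column per criterion in config order, raw
    scores; normalization is applied here.
    """
    config.validate()
    missing = set(config.criteria) - set(sources.columns)
    if missing:
        raise MCDAError(f"source table missing criteria: {sorted(missing)}")
    normalized = np.column_stack(
        [normalize_source(sources[c], config.normalization) for c in config.criteria]
    )
    final = config.scale_factor * normalized @ np.asarray(config.weights)
    return pd.Series(final, index=sources.index, name="final_score")


@dataclass
class MCDAResult:
    table: pd.DataFrame  # parameter, final_score, rank, tier, stampc_member
    config: MCDAConfig
    warnings: list[str] = field(default_factory=list)


def rank_and_tier(final_scores: pd.Series, config: MCDAConfig | None = None) -> MCDAResult:
    """Sort descending, assign ranks 1..n and tiers by threshold.

    Ties are broken by catalog order (the order of the incoming index for
    non-catalog parameters), each tied parameter receiving a consecutive
    rank.  Tier 1 is closed at t1 (score exactly t1 is Essential).
    """
    config = config or MCDAConfig()
    config.validate()
    t1, t2 = config.tier_thresholds
    order_key = {pid: i for i, pid in enumerate(final_scores.index)}
    ordered = sorted(
        final_scores.items(), key=lambda kv: (-kv[1], order_key[kv[0]])
    )
    rows = []
    for rank, (pid, score) in enumerate(ordered, start=1):
        tier = 1 if score >= t1 else 2 if score >= t2 else 3
        rows.append(
            {
                "parameter": pid,
                "final_score": float(score),
                "rank": rank,
                "tier": tier,
                "recommendation": TIER_RECOMMENDATION[tier],
            }
        )
    table = pd.DataFrame(rows).set_index("parameter")
    table["stampc_member"] = table["tier"] == 1
    return MCDAResult(table=table, config=config)


def stampc_panel(result: MCDAResult) -> dict[str, list[str]]:
    """Map the Tier-1 parameters onto the STAMP-C mnemonic letters.

    Returns letter -> list of parameter ids (C carries two).  If the Tier-1
    set differs from the canonical 7-parameter panel a warning is recorded
    on the result; the panel is still emitted from the tiers as computed.
    """
    tier1 = [pid for pid in result.table.index if result.table.loc[pid, "tier"] == 1]
    canonical = {
        pid for pid in PARAMETER_IDS if get_parameter(pid).stampc_letter is not None
    }
    if set(tier1) != canonical:
        msg = (
            f"Tier-1 set {sorted(tier1)} differs from the canonical "
            f"7-parameter STAMP-C panel"
        )
        result.warnings.append(msg)
        _warnings.warn(msg, stacklevel=2)
    panel: dict[str, list[str]] = {}
    for pid in tier1:
        letter = get_parameter(pid).stampc_letter if pid in canonical else None
        key = letter if letter is not None else "?"
        panel.setdefault(key, []).append(pid)
    return panel


@dataclass(frozen=True)
class SensitivityResult:
    n_draws: int
    concentration: float
    seed: int
    top_k: int
    top_k_stability: float
    mean_rank_correlation: float
    rank_quantiles: pd.DataFrame  # per-parameter rank distribution summary


def weight_sensitivity(
    sources: pd.DataFrame,
    config: MCDAConfig,
    n_draws: int = 500,
    concentration: float = 100.0,
    seed: int = 0,
) -> SensitivityResult:
    """Dirichlet weight-perturbation sensitivity analysis.

    Draws weight vectors from Dirichlet(concentration * baseline weights),
    recomputes the ranking per draw, and reports (a) the fraction of draws
    whose top-k identity set (k = baseline Tier-1 size) equals the
    baseline's and (b) the mean Kendall tau between each perturbed ranking
    and the baseline.
    """
    config.validate()
    if n_draws < 1:
        raise MCDAError("n_draws must be at least 1")
    if concentration <= 0:
        raise MCDAError("concentration must be positive")
    baseline_w = np.asarray(config.weights, dtype=float)
    if np.any(baseline_w == 0):
        raise MCDAError("baseline weights must be nonzero for Dirichlet centering")

    base = rank_and_tier(aggregate(sources, config), config)
    k = int((base.table["tier"] == 1).sum())
    base_top = set(base.table.index[base.table["rank"] <= k]) if k else set()
    base_ranks = base.table["rank"].reindex(sources.index).to_numpy()

    rng = np.random.default_rng(seed)
    stable = 0
    taus = np.empty(n_draws)
    all_ranks = np.empty((n_draws, len(sources.index)), dtype=int)
    from dataclasses import replace as _replace

    for d in range(n_draws):
        w = rng.dirichlet(concentration * baseline_w)
        cfg = _replace(config, weights=tuple(w))
        res = rank_and_tier(aggregate(sources, cfg), cfg)
        ranks = res.table["rank"].reindex(sources.index).to_numpy()
        all_ranks[d] = ranks
        top = set(res.table.index[res.table["rank"] <= k]) if k else set()
        if top == base_top:
            stable += 1
        taus[d] = kendalltau(base_ranks, ranks).statistic
    quantiles = pd.DataFrame(
        {
            "baseline_rank": base_ranks,
            "rank_p05": np.percentile(all_ranks, 5, axis=0),
            "rank_median": np.median(all_ranks, axis=0),
            "rank_p95": np.percentile(all_ranks, 95, axis=0),
        },
        index=sources.index,
    )
    return SensitivityResult(
        n_draws=n_draws,
        concentration=concentration,
        seed=seed,
        top_k=k,
        top_k_stability=stable / n_draws,
        mean_rank_correlation=float(np.mean(taus)),
        rank_quantiles=quantiles,
    )
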