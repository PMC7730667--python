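"""Case-dropping bootstrap stability and the CS coefficient.

How much of the sample can be dropped before the network changes?  For each
drop proportion q, B random subsamples of ceil((1-q) n) rows are drawn
without replacement, the network is re-estimated on each, and the Pearson
correlation of the subsample statistic vector with the full-sample vector is
recorded, for three statistics: the vectorized upper-triangle edge weights,
the thresholds tau, and the node strengths.

The correlation-stability coefficient CS(cor = 0.7) is the largest q at
which at least 95% of valid replicates still correlate >= 0.7 with the
full-sample vector; CS >= 0.2 is conventionally read as "reasonable"
stability and CS >= 0.5 as "excellent".

A replicate whose refit fails (e.g. a constant column in the subsample) or
whose correlation is undefined (zero-variance statistic vector on either
side) is recorded as NaN and excluded from the valid count.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .data_model import SymptomDataset
from .ising_elasso import ElassoConfig, EstimationError, IsingNetwork, fit_ising_elasso

logger = logging.getLogger(__name__)

STATISTICS = ("edges", "thresholds", "strength")

#: Default case-drop grid: 5% to 70% of the sample, in 5% steps.
DEFAULT_DROP_PROPORTIONS = tuple(np.round(np.arange(0.05, 0.7001, 0.05), 2))


def _stat_vectors(net: IsingNetwork) -> dict[str, np.ndarray]:
    iu = np.triu_indices(net.p, 1)
    return {
        "edges": net.beta[iu],
        "thresholds": net.tau,
        "strength": np.abs(net.beta).sum(axis=1),
    }


def _correlation(a: np.ndarray, b: np.ndarray, method: str) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    if method == "spearman":
        return float(sstats.spearmanr(a, b).statistic)
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class StabilityResult:
    """Per-proportion bootstrap correlations and CS coefficients."""

    drop_proportions: tuple[float, ...]
    correlations: dict[str, np.ndarray]  # statistic -> (n_props, B), NaN = invalid
    B: int
    seed: int
    cor_threshold: float = 0.7
    certainty: float = 0.95
    n_failed_refits: int = 0
    cs: dict[str, float] = field(default_factory=dict)

    def cs_labels(self) -> dict[str, str]:
        return {k: cs_label(v) for k, v in self.cs.items()}

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for stat, mat in self.correlations.items():
            for i, q in enumerate(self.drop_proportions):
                for b in range(self.B):
                    rows.append((q, b, stat, mat[i, b]))
        return pd.DataFrame(
            rows, columns=["drop_proportion", "replicate", "statistic",
                           "correlation"]
        )

    def summary(self) -> dict:
        return {
            "B": self.B,
            "seed": self.seed,
            "cor_threshold": self.cor_threshold,
            "certainty": self.certainty,
            "drop_proportions": list(self.drop_proportions),
            "n_failed_refits": self.n_failed_refits,
            "cs": {k: (None if np.isnan(v) else v) for k, v in self.cs.items()},
            "labels": self.cs_labels(),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2))


def cs_label(cs: float) -> str:
    if np.isnan(cs):
        return "not estimable"
    if cs >= 0.5:
        return "excellent"
    if cs >= 0.2:
        return "reasonable"
    return "unstable"


def cs_coefficient(
    correlations: dict[float, np.ndarray],
    cor_threshold: float = 0.7,
    certainty: float = 0.95,
) -> float:
    """CS coefficient from a {drop proportion: correlation array} table.

    The largest proportion at which at least ``certainty`` of the valid
    (non-NaN) replicates correlate >= ``cor_threshold``; 0.0 if no
    proportion qualifies; NaN if every replicate everywhere is invalid.
    """
    any_valid = False
    best = 0.0
    for q in sorted(correlations):
        vals = np.asarray(correlations[q], dtype=float)
        valid = vals[~np.isnan(vals)]
        if valid.size == 0:
            continue
        any_valid = True
        if np.mean(valid >= cor_threshold) >= certainty:
            best = max(best, float(q))
    if not any_valid:
        return float("nan")
    return best


def case_drop_bootstrap(
    ds: SymptomDataset,
    cfg: ElassoConfig | None = None,
    drop_proportions: tuple[float, ...] = DEFAULT_DROP_PROPORTIONS,
    B: int = 1000,
    seed: int = 0,
    correlation: str = "pearson",
    cor_threshold: float = 0.7,
    certainty: float = 0.95,
) -> StabilityResult:
    """Case-dropping bootstrap of edge weights, thresholds and strength."""
    cfg = cfg or ElassoConfig()
    if B < 1:
        raise ValueError("B must be >= 1")
    qs = tuple(float(q) for q in drop_proportions)
    if any(not (0 < q < 1) for q in qs) or list(qs) != sorted(qs):
        raise ValueError("drop proportions must be increasing and in (0, 1)")
    n, p = ds.n, ds.p
    if any(int(np.ceil((1 - q) * n)) < p + 5 for q in qs):
        raise ValueError("largest drop proportion leaves fewer than p + 5 rows")
    full = _stat_vectors(fit_ising_elasso(ds, cfg))
    for stat, v in full.items():
        if np.std(v) == 0:
            logger.warning(
                "full-sample %s vector has zero variance; its correlations "
                "are not estimable", stat,
            )
    rng = np.random.default_rng(seed)
    cors = {s: np.full((len(qs), B), np.nan) for s in STATISTICS}
    failed = 0
    for i, q in enumerate(qs):
        keep = int(np.ceil((1 - q) * n))
        for b in range(B):
            rows = rng.choice(n, size=keep, replace=False)
            try:
                sub = _stat_vectors(fit_ising_elasso(ds.subset(rows), cfg))
            except EstimationError:
                failed += 1
                continue
            for stat in STATISTICS:
                cors[stat][i, b] = _correlation(
                    full[stat], sub[stat], correlation
                )
    if failed:
        logger.warning("%d replicate refit(s) failed and were excluded", failed)
    cs = {
        stat: cs_coefficient(
            {q: cors[stat][i] for i, q in enumerate(qs)},
            cor_threshold, certainty,
        )
        for stat in STATISTICS
    }
    return StabilityResult(
        drop_proportions=qs,
        correlations=cors,
        B=B,
        seed=seed,
        cor_threshold=cor_threshold,
        certainty=certainty,
        n_failed_refits=failed,
        cs=cs,
    )
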