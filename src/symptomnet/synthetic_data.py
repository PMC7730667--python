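"""Ground-truth Ising models, exact/Gibbs samplers, and study emulation.

The pairwise binary Markov random field used throughout this package is
parameterized on {0,1}^p:

    P(x) = exp( sum_j tau_j x_j + sum_{j<k} beta_jk x_j x_k ) / Z.

For p <= 20 the normalizer Z is computed by exhaustive enumeration, which
gives exact sampling, exact marginals, and a root-finding target for
calibrating thresholds to prescribed endorsement rates.  A Gibbs sampler
covers larger p.

``emulate_study`` generates a stand-in for the raw data of a community
survey of 555 older adults (Madrid, ages 65-84) interviewed with the
CIDI65+ for the nine DSM major-depression criteria: gender strata of
288 women / 267 men with the published per-stratum symptom endorsement
rates, age-group labels (65-74 / 75-84) at sizes 296 / 259, and pairwise
symptom dependence from planted sparse coupling structures.  The planted
structures echo the qualitative findings reported for that survey (a
depressed-mood hub for women; fatigue- and sleep-centered sub-networks for
men); they are illustrative, not a reconstruction of the unpublished
estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numba
import numpy as np
import pandas as pd

from .data_model import SymptomCodebook, SymptomDataset

_ENUM_LIMIT = 20  # 2^20 states is the largest enumeration we allow


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class IsingModelSpec:
    """Ground-truth thresholds tau and symmetric couplings beta."""

    tau: np.ndarray
    beta: np.ndarray
    labels: SymptomCodebook = field(default_factory=SymptomCodebook)

    def __post_init__(self) -> None:
        object.__setattr__(self, "tau", np.asarray(self.tau, dtype=float))
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        p = self.tau.shape[0]
        if self.beta.shape != (p, p):
            raise ValueError("beta must be p x p matching tau")
        if not (np.isfinite(self.tau).all() and np.isfinite(self.beta).all()):
            raise ValueError("parameters must be finite")
        if not np.allclose(self.beta, self.beta.T):
            raise ValueError("beta must be symmetric")
        if np.any(np.diag(self.beta) != 0):
            raise ValueError("beta must have a zero diagonal")

    @property
    def p(self) -> int:
        return self.tau.shape[0]


@dataclass(frozen=True)
class StateDistribution:
    """Exact probabilities over all 2^p states.

    State ordering: state index s encodes the configuration with node 0 as
    the least significant bit, i.e. ``states()[s, j] == (s >> j) & 1``.
    """

    probabilities: np.ndarray
    p: int

    def __post_init__(self) -> None:
        pr = np.asarray(self.probabilities, dtype=float)
        if pr.shape != (2**self.p,):
            raise ValueError("need one probability per state")
        if (pr < 0).any() or abs(pr.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must be >= 0 and sum to 1")
        object.__setattr__(self, "probabilities", pr)

    def states(self) -> np.ndarray:
        return _all_states(self.p)

    def marginals(self) -> np.ndarray:
        return self.states().T.astype(float) @ self.probabilities


def _all_states(p: int) -> np.ndarray:
    return ((np.arange(2**p)[:, None] >> np.arange(p)) & 1).astype(np.int8)


def enumerate_distribution(spec: IsingModelSpec) -> StateDistribution:
    """Exact state distribution by enumerating all 2^p configurations."""
    if spec.p > _ENUM_LIMIT:
        raise ValueError(
            f"p={spec.p} > {_ENUM_LIMIT}: enumeration of 2^p states refused; "
            "use the Gibbs sampler instead"
        )
    s = _all_states(spec.p).astype(float)
    logw = s @ spec.tau + 0.5 * np.einsum("ij,jk,ik->i", s, spec.beta, s)
    logw -= logw.max()
    w = np.exp(logw)
    return StateDistribution(w / w.sum(), spec.p)


@numba.njit(cache=True)
def _gibbs_kernel(tau, beta, n, burn_in, thin, seed):
    np.random.seed(seed)
    p = tau.shape[0]
    x = (np.random.random(p) < 0.5).astype(np.int8)
    out = np.empty((n, p), dtype=np.int8)
    total_sweeps = burn_in + n * thin
    k = 0
    for sweep in range(total_sweeps):
        for j in range(p):
            eta = tau[j]
            for m in range(p):
                if m != j:
                    eta += beta[j, m] * x[m]
            pj = 1.0 / (1.0 + np.exp(-eta))
            x[j] = 1 if np.random.random() < pj else 0
        if sweep >= burn_in and (sweep - burn_in) % thin == 0:
            out[k] = x
            k += 1
            if k == n:
                break
    return out


def sample(
    spec: IsingModelSpec,
    n: int,
    seed: int,
    method: str = "exact",
    burn_in: int = 1000,
    thin: int = 10,
) -> SymptomDataset:
    """Draw n configurations from the model.

    ``exact`` (p <= 20) draws i.i.d. states from the enumerated
    distribution; ``gibbs`` runs a single-site Gibbs chain (one sample per
    ``thin`` full sweeps after ``burn_in`` sweeps).  Deterministic given
    the seed.
    """
    if method == "exact":
        dist = enumerate_distribution(spec)
        rng = np.random.default_rng(seed)
        idx = rng.choice(2**spec.p, size=n, p=dist.probabilities)
        values = dist.states()[idx]
    elif method == "gibbs":
        values = _gibbs_kernel(
            spec.tau, spec.beta, n, burn_in, thin, seed % (2**31 - 1)
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return SymptomDataset(values, spec.labels)


def calibrate_thresholds(
    beta: np.ndarray,
    target_marginals: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
    damping: float = 1.0,
    labels: SymptomCodebook | None = None,
) -> np.ndarray:
    """Thresholds tau such that the model's exact marginals hit the targets.

    Damped fixed-point iteration on the marginal map: each step moves tau_j
    by the logit gap between target and current marginal.  With beta = 0 the
    closed form tau_j = logit(target_j) is returned directly.
    """
    beta = np.asarray(beta, dtype=float)
    t = np.asarray(target_marginals, dtype=float)
    if ((t <= 0) | (t >= 1)).any():
        raise ValueError("target marginals must lie strictly in (0, 1)")
    p = t.shape[0]
    labels = labels or SymptomCodebook(
        tuple((f"V{i}", f"variable {i}") for i in range(p))
    )
    logit_t = np.log(t / (1 - t))
    if not beta.any():
        return logit_t
    tau = logit_t.copy()
    for _ in range(max_iter):
        m = enumerate_distribution(IsingModelSpec(tau, beta, labels)).marginals()
        gap = np.abs(m - t).max()
        if gap < tol:
            return tau
        tau = tau + damping * (logit_t - np.log(m / (1 - m)))
    raise ConvergenceError(
        f"threshold calibration did not reach tol={tol} in {max_iter} "
        f"iterations (worst marginal gap {gap:.2e})"
    )


# --------------------------------------------------------------------------
# study emulation

#: Stratum sizes of the emulated survey (N = 555).
STUDY_SIZES = {"female": 288, "male": 267, "65-74": 296, "75-84": 259}

#: Published per-stratum symptom endorsement rates (codebook order:
#: DM, LI, AW, SD, PAR, FE, FW, C, SU).
STUDY_PREVALENCE = {
    "female": np.array([0.45, 0.27, 0.23, 0.36, 0.14, 0.34, 0.24, 0.23, 0.19]),
    "male": np.array([0.20, 0.14, 0.10, 0.16, 0.10, 0.13, 0.11, 0.10, 0.07]),
}


def _planted_beta(codebook: SymptomCodebook, edges: dict[tuple[str, str], float]
                  ) -> np.ndarray:
    p = len(codebook)
    beta = np.zeros((p, p))
    for (a, b), w in edges.items():
        j, k = codebook.index(a), codebook.index(b)
        beta[j, k] = beta[k, j] = w
    return beta


def study_specs(codebook: SymptomCodebook | None = None
                ) -> dict[str, IsingModelSpec]:
    """Gender-specific ground-truth models for the study emulation.

    Female: a depressed-mood hub (DM-FE strongest, then DM-PAR, DM-SD) with
    weaker SD-SU, LI-FE and PAR-C links.  Male: two sub-structures, one of
    SU/LI/AW tied to FE and one of PAR/DM/FW tied to SD.  Thresholds are
    calibrated so exact marginals equal the published stratum prevalences.
    """
    codebook = codebook or SymptomCodebook.default()
    female_edges = {
        ("DM", "FE"): 1.2, ("DM", "PAR"): 0.9, ("DM", "SD"): 0.9,
        ("SD", "SU"): 0.6, ("LI", "FE"): 0.6, ("PAR", "C"): 0.6,
    }
    male_edges = {
        ("FE", "SU"): 1.2, ("FE", "LI"): 1.2, ("FE", "AW"): 1.2,
        ("SD", "PAR"): 1.2, ("SD", "DM"): 0.9, ("SD", "FW"): 0.9,
    }
    out = {}
    for level, edges in (("female", female_edges), ("male", male_edges)):
        beta = _planted_beta(codebook, edges)
        tau = calibrate_thresholds(
            beta, STUDY_PREVALENCE[level], labels=codebook
        )
        out[level] = IsingModelSpec(tau, beta, codebook)
    return out


def emulate_study(
    seed: int,
    codebook: SymptomCodebook | None = None,
    return_truth: bool = False,
):
    """Synthetic stand-in for the survey's raw respondent-level data.

    Samples 288 'female' and 267 'male' rows exactly from the calibrated
    gender-specific models, then assigns age-group labels by a seeded
    permutation within gender at fixed totals 296 (65-74) / 259 (75-84).
    Deterministic given the seed.  With ``return_truth=True`` also returns
    the ground-truth specs and the calibration report.
    """
    codebook = codebook or SymptomCodebook.default()
    specs = study_specs(codebook)
    rng = np.random.default_rng(seed)
    # age totals split across genders proportionally (154 + 142 = 296)
    young = {"female": 154, "male": 142}
    parts, covs = [], []
    for level in ("female", "male"):
        n = STUDY_SIZES[level]
        sub_seed = int(rng.integers(0, 2**31 - 1))
        ds = sample(specs[level], n, seed=sub_seed, method="exact")
        ages = np.array(["65-74"] * young[level]
                        + ["75-84"] * (n - young[level]), dtype=object)
        rng.shuffle(ages)
        parts.append(ds.values)
        covs.append(pd.DataFrame({"gender": level, "age_group": ages}))
    dataset = SymptomDataset(
        np.vstack(parts), codebook, pd.concat(covs, ignore_index=True)
    )
    if not return_truth:
        return dataset
    truth = {
        "seed": seed,
        "strata": {
            level: {
                "n": STUDY_SIZES[level],
                "tau": specs[level].tau.tolist(),
                "beta": specs[level].beta.tolist(),
                "target_marginals": STUDY_PREVALENCE[level].tolist(),
            }
            for level in ("female", "male")
        },
        "age_sizes": {"65-74": 296, "75-84": 259},
    }
    return dataset, truth


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2))
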