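"""Five-state copy-number HMM over LRR/BAF marker signals.

The hidden states are integer copy numbers 0-4 with diploid CN2 as the null.
Emissions combine a Gaussian on the log R ratio (total intensity) with a
state-specific mixture over B-allele-frequency clusters:

* CN0 - no allelic signal, BAF ~ uniform on [0, 1];
* CN1 - genotypes A/B, clusters {0, 1};
* CN2 - AA/AB/BB, clusters {0, 1/2, 1};
* CN3 - clusters {0, 1/3, 2/3, 1};
* CN4 - clusters {0, 1/4, 1/2, 3/4, 1}.

Cluster components are normal with a common sd, truncated to [0, 1]; the
boundary clusters at 0 and 1 therefore behave as folded half-normals, which
absorbs the point masses that clipped homozygous markers produce.

Transitions are a sticky diagonal (``stay_prob``) with the remaining mass
spread uniformly; chromosomes are decoded independently by Viterbi.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .calls import MarkerSignalTable

__all__ = ["HmmModel", "emission_loglik", "log_emission_matrix", "viterbi_path", "log_bayes_factor"]

STATES: tuple[int, ...] = (0, 1, 2, 3, 4)
LN10 = math.log(10.0)

# BAF cluster means per state; None marks the uniform (CN0) emission.
_DEFAULT_BAF_CLUSTERS: tuple[Optional[tuple[float, ...]], ...] = (
    None,
    (0.0, 1.0),
    (0.0, 0.5, 1.0),
    (0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0),
    (0.0, 0.25, 0.5, 0.75, 1.0),
)


def _default_lrr_means() -> np.ndarray:
    return np.array([-3.0, -0.45, 0.0, 0.30, 0.55])


def _default_lrr_sds() -> np.ndarray:
    return np.full(5, 0.15)


def _default_priors() -> np.ndarray:
    return np.array([0.001, 0.001, 0.996, 0.001, 0.001])


@dataclass
class HmmModel:
    """Parameters of the copy-number HMM; defaults are config-overridable."""

    lrr_means: np.ndarray = field(default_factory=_default_lrr_means)
    lrr_sds: np.ndarray = field(default_factory=_default_lrr_sds)
    baf_clusters: tuple[Optional[tuple[float, ...]], ...] = _DEFAULT_BAF_CLUSTERS
    baf_sd: float = 0.03
    stay_prob: float = 0.999
    state_priors: np.ndarray = field(default_factory=_default_priors)

    def __post_init__(self) -> None:
        self.lrr_means = np.asarray(self.lrr_means, dtype=float)
        self.lrr_sds = np.asarray(self.lrr_sds, dtype=float)
        self.state_priors = np.asarray(self.state_priors, dtype=float)
        if self.lrr_means.shape != (5,) or self.lrr_sds.shape != (5,):
            raise ValueError("lrr_means and lrr_sds must have 5 entries (CN0..CN4)")
        if (self.lrr_sds <= 0).any() or self.baf_sd <= 0:
            raise ValueError("standard deviations must be positive")
        if not 0 < self.stay_prob < 1:
            raise ValueError("stay_prob must be in (0, 1)")
        if abs(self.state_priors.sum() - 1.0) > 1e-9 or (self.state_priors <= 0).any():
            raise ValueError("state_priors must be positive and sum to 1")

    @property
    def log_transition(self) -> np.ndarray:
        off = (1.0 - self.stay_prob) / 4.0
        mat = np.full((5, 5), off)
        np.fill_diagonal(mat, self.stay_prob)
        return np.log(mat)

    @classmethod
    def from_dict(cls, overrides: dict) -> "HmmModel":
        """Build a model from a (possibly partial) parameter mapping."""
        kwargs = {}
        for key in ("lrr_means", "lrr_sds", "state_priors"):
            if key in overrides:
                kwargs[key] = np.asarray(overrides[key], dtype=float)
        for key in ("baf_sd", "stay_prob"):
            if key in overrides:
                kwargs[key] = float(overrides[key])
        if "baf_clusters" in overrides:
            kwargs["baf_clusters"] = tuple(
                None if c is None else tuple(float(x) for x in c)
                for c in overrides["baf_clusters"]
            )
        return cls(**kwargs)


def _baf_logdensity(baf: np.ndarray, clusters: Optional[tuple[float, ...]], sd: float) -> np.ndarray:
    """Log density of the state's BAF mixture, vectorised over markers."""
    if clusters is None:
        return np.zeros_like(baf)  # uniform on [0, 1]
    parts = []
    log_weight = -math.log(len(clusters))
    for mean in clusters:
        # truncation of each component to [0, 1]
        log_z = math.log(norm.cdf((1.0 - mean) / sd) - norm.cdf((0.0 - mean) / sd))
        parts.append(log_weight + norm.logpdf(baf, mean, sd) - log_z)
    return logsumexp(np.stack(parts, axis=0), axis=0)


def log_emission_matrix(lrr: np.ndarray, baf: np.ndarray, model: HmmModel) -> np.ndarray:
    """Natural-log emission densities, shape ``(n_markers, 5)``."""
    lrr = np.asarray(lrr, dtype=float)
    baf = np.asarray(baf, dtype=float)
    out = np.empty((lrr.size, 5))
    for s in STATES:
        out[:, s] = norm.logpdf(lrr, model.lrr_means[s], model.lrr_sds[s])
        out[:, s] += _baf_logdensity(baf, model.baf_clusters[s], model.baf_sd)
    return out


def emission_loglik(marker: tuple[float, float], state: int, model: HmmModel) -> float:
    """Natural-log emission density of one ``(lrr, baf)`` marker under ``state``."""
    if state not in STATES:
        raise ValueError(f"unknown copy-number state {state!r}")
    lrr, baf = marker
    if not 0.0 <= baf <= 1.0:
        raise ValueError(f"BAF must lie in [0, 1], got {baf}")
    return float(log_emission_matrix(np.array([lrr]), np.array([baf]), model)[0, state])


def _viterbi(log_em: np.ndarray, log_prior: np.ndarray, log_trans: np.ndarray) -> tuple[np.ndarray, float]:
    """Max-product decoding; returns (state indices, log joint probability)."""
    n, n_states = log_em.shape
    if n == 0:
        return np.empty(0, dtype=int), 0.0
    delta = log_prior + log_em[0]
    psi = np.zeros((n, n_states), dtype=int)
    for t in range(1, n):
        scores = delta[:, None] + log_trans
        psi[t] = scores.argmax(axis=0)
        delta = scores.max(axis=0) + log_em[t]
    path = np.empty(n, dtype=int)
    path[-1] = int(delta.argmax())
    for t in range(n - 1, 0, -1):
        path[t - 1] = psi[t, path[t]]
    return path, float(delta.max())


def viterbi_path(signals: MarkerSignalTable, model: HmmModel) -> np.ndarray:
    """Per-marker copy-number states (joint maximum-probability sequence).

    Chromosomes are decoded independently; the result is aligned to the
    marker order of ``signals``.
    """
    log_prior = np.log(model.state_priors)
    log_trans = model.log_transition
    pieces = []
    for _, _, lrr, baf in signals.iter_chromosomes():
        log_em = log_emission_matrix(lrr, baf, model)
        path, _ = _viterbi(log_em, log_prior, log_trans)
        pieces.append(path)
    if not pieces:
        return np.empty(0, dtype=int)
    return np.concatenate(pieces)


def log_bayes_factor(lrr: np.ndarray, baf: np.ndarray, state: int, model: HmmModel) -> float:
    """Segment evidence: summed per-marker log10 emission ratio of ``state`` vs CN2.

    Non-negative whenever the called state is the per-marker argmax
    everywhere; additive over markers by construction.
    """
    if state not in STATES:
        raise ValueError(f"unknown copy-number state {state!r}")
    log_em = log_emission_matrix(np.asarray(lrr), np.asarray(baf), model)
    return float((log_em[:, state] - log_em[:, 2]).sum() / LN10)
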