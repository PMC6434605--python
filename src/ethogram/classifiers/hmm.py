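"""Hidden Markov model with constrained transitions and mixed emissions.

Observations are bin means (5 s murre, 10 s kittiwake) of pitch, the
species activity metric and WBF, plus a below--1 m depth indicator for
murres.  Each hidden state is a behavior (kittiwakes carry two colony
states, merged after decoding).  Emission families: Normal for pitch,
Exponential for murre SD_ODBA, zero-inflated log-normal for WBF and
kittiwake SD_Z (a point mass at zero with probability pi plus a
log-normal on positive values), and a fixed Bernoulli for the depth
indicator that anchors the diving state.

Transitions that are behaviorally impossible -- colony<->swimming,
colony<->diving and flying<->diving -- are structurally zero: they start
at zero and remain exactly zero through Baum-Welch re-estimation (the
expected count of a zero-probability transition is zero).  Decoding is
by the Viterbi algorithm; decoded bins are expanded back to the 1-s
grid by repetition.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml
from numba import njit

from ..config import SpeciesConfig
from ..io import DataError
from .common import make_ethogram

__all__ = ["HmmSpec", "bin_features", "fit_hmm", "classify_hmm"]

_LOG_FLOOR = -1e6
_ZERO_EPS = 1e-8


# ---------------------------------------------------------------- kernels

@njit(cache=False)
def _forward_backward(loga, logpi, logb):
    """Log-space forward-backward.

    Returns (log-likelihood, gamma[T,K], xi_sum[K,K]) where xi_sum is
    the expected transition-count matrix in probability space.
    """
    T, K = logb.shape
    alpha = np.empty((T, K))
    beta = np.empty((T, K))
    for k in range(K):
        alpha[0, k] = logpi[k] + logb[0, k]
    for t in range(1, T):
        for j in range(K):
            m = -np.inf
            for i in range(K):
                v = alpha[t - 1, i] + loga[i, j]
                if v > m:
                    m = v
            s = 0.0
            if m > -np.inf:
                for i in range(K):
                    s += np.exp(alpha[t - 1, i] + loga[i, j] - m)
            alpha[t, j] = m + np.log(s) + logb[t, j] if s > 0 else -np.inf
    m = -np.inf
    for k in range(K):
        if alpha[T - 1, k] > m:
            m = alpha[T - 1, k]
    s = 0.0
    for k in range(K):
        s += np.exp(alpha[T - 1, k] - m)
    loglik = m + np.log(s)

    for k in range(K):
        beta[T - 1, k] = 0.0
    for t in range(T - 2, -1, -1):
        for i in range(K):
            m2 = -np.inf
            for j in range(K):
                v = loga[i, j] + logb[t + 1, j] + beta[t + 1, j]
                if v > m2:
                    m2 = v
            s2 = 0.0
            if m2 > -np.inf:
                for j in range(K):
                    s2 += np.exp(loga[i, j] + logb[t + 1, j] + beta[t + 1, j] - m2)
            beta[t, i] = m2 + np.log(s2) if s2 > 0 else -np.inf

    gamma = np.empty((T, K))
    for t in range(T):
        mg = -np.inf
        for k in range(K):
            gamma[t, k] = alpha[t, k] + beta[t, k]
            if gamma[t, k] > mg:
                mg = gamma[t, k]
        sg = 0.0
        for k in range(K):
            sg += np.exp(gamma[t, k] - mg)
        for k in range(K):
            gamma[t, k] = np.exp(gamma[t, k] - mg) / sg

    xi = np.zeros((K, K))
    for t in range(T - 1):
        mx = -np.inf
        for i in range(K):
            for j in range(K):
                v = alpha[t, i] + loga[i, j] + logb[t + 1, j] + beta[t + 1, j]
                if v > mx:
                    mx = v
        sx = 0.0
        for i in range(K):
            for j in range(K):
                sx += np.exp(alpha[t, i] + loga[i, j] + logb[t + 1, j]
                             + beta[t + 1, j] - mx)
        for i in range(K):
            for j in range(K):
                xi[i, j] += np.exp(alpha[t, i] + loga[i, j] + logb[t + 1, j]
                                   + beta[t + 1, j] - mx) / sx
    return loglik, gamma, xi


@njit(cache=False)
def _viterbi(loga, logpi, logb):
    T, K = logb.shape
    delta = np.empty((T, K))
    back = np.zeros((T, K), dtype=np.int32)
    for k in range(K):
        delta[0, k] = logpi[k] + logb[0, k]
    for t in range(1, T):
        for j in range(K):
            best = -np.inf
            arg = 0
            for i in range(K):
                v = delta[t - 1, i] + loga[i, j]
                if v > best:
                    best = v
                    arg = i
            delta[t, j] = best + logb[t, j]
            back[t, j] = arg
    path = np.empty(T, dtype=np.int32)
    best = -np.inf
    for k in range(K):
        if delta[T - 1, k] > best:
            best = delta[T - 1, k]
            path[T - 1] = k
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


# ------------------------------------------------------------------ spec

@dataclass
class HmmSpec:
    """States, emission parameters and transition structure of the HMM."""

    states: list[str]
    variables: dict                 # name -> {"family": ..., params: {state: value}}
    forbidden: list[tuple[str, str]]
    state_map: dict[str, str]       # decoded state -> reported behavior
    bin_s: float = 5.0

    @classmethod
    def preset(cls, config: SpeciesConfig) -> "HmmSpec":
        name = f"hmm_{config.species}.yaml"
        ref = resources.files("ethogram").joinpath(f"presets/{name}")
        with ref.open() as fh:
            raw = yaml.safe_load(fh)
        return cls(states=list(raw["states"]), variables=raw["variables"],
                   forbidden=[tuple(p) for p in raw["forbidden_transitions"]],
                   state_map=dict(raw["state_map"]), bin_s=config.hmm_bin)

    def transition_mask(self) -> np.ndarray:
        """Boolean matrix: True where a transition is allowed."""
        k = len(self.states)
        mask = np.ones((k, k), dtype=bool)
        idx = {s: i for i, s in enumerate(self.states)}
        for a, b in self.forbidden:
            mask[idx[a], idx[b]] = False
        return mask

    def initial_transitions(self, self_mass: float = 0.99) -> np.ndarray:
        """Self-transition-heavy start, uniform over allowed off-diagonals."""
        mask = self.transition_mask()
        k = len(self.states)
        A = np.zeros((k, k))
        for i in range(k):
            allowed = np.nonzero(mask[i])[0]
            off = allowed[allowed != i]
            A[i, i] = self_mass if i in allowed else 0.0
            if off.size:
                A[i, off] = (1.0 - A[i, i]) / off.size
            A[i] /= A[i].sum()
        return A

    def param_arrays(self) -> dict:
        """Emission parameters as {variable: {param: array over states}}."""
        out = {}
        for var, d in self.variables.items():
            out[var] = {"family": d["family"], "fixed": bool(d.get("fixed", False))}
            for key, values in d.items():
                if key in ("family", "fixed"):
                    continue
                out[var][key] = np.array([float(values[s]) for s in self.states])
        return out


def bin_features(features: pd.DataFrame, config: SpeciesConfig,
                 bin_s: Optional[float] = None) -> pd.DataFrame:
    """Bin the 1-s feature grid to the HMM observation interval.

    Continuous variables are bin means; depth becomes an indicator of
    any second in the bin being below the dive threshold.
    """
    b = int(round(bin_s if bin_s is not None else config.hmm_bin))
    n = len(features)
    idx = np.arange(n) // b
    g = features.groupby(idx)
    out = pd.DataFrame({
        "pitch": g["pitch"].mean().to_numpy(),
        "activity": g[config.activity_metric].mean().to_numpy(),
        "wbf": g["WBF"].mean().to_numpy(),
    })
    if config.has_depth:
        if "depth" not in features.columns:
            raise DataError("depth channel required for a diving species")
        below = (features["depth"].to_numpy()
                 < config.dive_depth_threshold).astype(float)
        out["depth"] = (pd.Series(below).groupby(idx).max().to_numpy())
    out.attrs["bin_s"] = b
    out.attrs["n_seconds"] = n
    return out


def _emission_loglik(obs: pd.DataFrame, params: dict, states: list) -> np.ndarray:
    T, K = len(obs), len(states)
    logb = np.zeros((T, K))
    for var, p in params.items():
        x = obs[var].to_numpy(dtype=float)
        fam = p["family"]
        if fam == "normal":
            mean, sd = p["mean"], np.maximum(p["sd"], 1e-3)
            ll = (-0.5 * ((x[:, None] - mean[None, :]) / sd[None, :]) ** 2
                  - np.log(sd[None, :] * np.sqrt(2 * np.pi)))
        elif fam == "exponential":
            rate = np.maximum(p["rate"], 1e-6)
            xe = np.maximum(x, 0.0)
            ll = np.log(rate[None, :]) - rate[None, :] * xe[:, None]
        elif fam == "zi_lognormal":
            loc = np.maximum(p["location"], 1e-6)
            scale = np.maximum(p["scale"], 0.02)
            pi = np.clip(p["zero_mass"], 1e-9, 1 - 1e-9)
            zero = x < _ZERO_EPS
            xl = np.log(np.maximum(x, _ZERO_EPS))
            pos_ll = (-0.5 * ((xl[:, None] - np.log(loc)[None, :])
                              / scale[None, :]) ** 2
                      - np.log(scale[None, :] * np.sqrt(2 * np.pi))
                      - xl[:, None])
            ll = np.where(zero[:, None], np.log(pi)[None, :],
                          np.log1p(-pi)[None, :] + pos_ll)
        elif fam == "bernoulli":
            pr = np.clip(p["p"], 1e-13, 1 - 1e-13)
            xb = (x > 0.5).astype(float)
            ll = (xb[:, None] * np.log(pr)[None, :]
                  + (1 - xb[:, None]) * np.log1p(-pr)[None, :])
        else:
            raise ValueError(f"unknown emission family {fam!r}")
        if not np.all(np.isfinite(ll)):
            bad = ~np.all(np.isfinite(ll), axis=1)
            if np.any(~np.isfinite(x)):
                raise DataError(f"non-finite observations in variable {var!r}")
            ll = np.where(np.isfinite(ll), ll, _LOG_FLOOR)
        logb += ll
    return np.maximum(logb, _LOG_FLOOR)


def _m_step(params: dict, obs_all: list, gammas: list) -> None:
    G = np.concatenate(gammas, axis=0)            # (T_total, K)
    for var, p in params.items():
        if p["fixed"]:
            continue
        x = np.concatenate([o[var].to_numpy(dtype=float) for o in obs_all])
        w_tot = G.sum(axis=0)
        fam = p["family"]
        if fam == "normal":
            ok = w_tot > 1e-6
            mean = np.where(ok, (G * x[:, None]).sum(axis=0) / np.maximum(w_tot, 1e-12),
                            p["mean"])
            var_ = (G * (x[:, None] - mean[None, :]) ** 2).sum(axis=0) \
                / np.maximum(w_tot, 1e-12)
            p["mean"] = mean
            p["sd"] = np.where(ok, np.sqrt(np.maximum(var_, 1e-6)), p["sd"])
        elif fam == "exponential":
            ok = w_tot > 1e-6
            mean = (G * np.maximum(x, 1e-9)[:, None]).sum(axis=0) \
                / np.maximum(w_tot, 1e-12)
            p["rate"] = np.where(ok, 1.0 / np.maximum(mean, 1e-9), p["rate"])
        elif fam == "zi_lognormal":
            zero = (x < _ZERO_EPS).astype(float)
            w_zero = (G * zero[:, None]).sum(axis=0)
            ok = w_tot > 1e-6
            p["zero_mass"] = np.where(
                ok, np.clip(w_zero / np.maximum(w_tot, 1e-12), 1e-6, 1 - 1e-6),
                p["zero_mass"])
            pos = x >= _ZERO_EPS
            if np.any(pos):
                Gp = G[pos]
                xl = np.log(x[pos])
                wp = Gp.sum(axis=0)
                okp = wp > 1e-6
                mu = (Gp * xl[:, None]).sum(axis=0) / np.maximum(wp, 1e-12)
                v = (Gp * (xl[:, None] - mu[None, :]) ** 2).sum(axis=0) \
                    / np.maximum(wp, 1e-12)
                p["location"] = np.where(okp, np.exp(mu), p["location"])
                p["scale"] = np.where(okp, np.sqrt(np.maximum(v, 4e-4)), p["scale"])


def fit_hmm(obs_list: list, spec: HmmSpec, max_iter: int = 10,
            tol: float = 1e-4):
    """Baum-Welch fit over one or more binned observation sequences.

    Returns (params, transition matrix, initial distribution,
    log-likelihood trace).  Forbidden transitions remain exactly zero;
    fixed emission families (the depth Bernoulli) are not re-estimated.
    """
    params = spec.param_arrays()
    A = spec.initial_transitions()
    K = len(spec.states)
    pi0 = np.full(K, 1.0 / K)
    mask = spec.transition_mask()
    hist = []
    for it in range(max_iter):
        with np.errstate(divide="ignore"):
            loga = np.where(A > 0, np.log(np.maximum(A, 1e-300)), -np.inf)
            logpi = np.where(pi0 > 0, np.log(np.maximum(pi0, 1e-300)), -np.inf)
        total = 0.0
        gammas, xis, starts = [], np.zeros((K, K)), np.zeros(K)
        for obs in obs_list:
            logb = _emission_loglik(obs, params, spec.states)
            if not np.isfinite(logb[0]).any():
                raise DataError("likelihood non-finite at the first bin")
            ll, gamma, xi = _forward_backward(loga, logpi, logb)
            total += ll
            gammas.append(gamma)
            xis += xi
            starts += gamma[0]
        hist.append(total)
        if it > 0 and abs(hist[-1] - hist[-2]) < tol * (1 + abs(hist[-2])):
            break
        # M step
        _m_step(params, obs_list, gammas)
        xis[~mask] = 0.0
        rows = xis.sum(axis=1)
        A = np.where(rows[:, None] > 1e-12, xis / np.maximum(rows[:, None], 1e-12), A)
        pi0 = starts / starts.sum()
    return params, A, pi0, hist


def decode(obs: pd.DataFrame, params: dict, A: np.ndarray, pi0: np.ndarray,
           spec: HmmSpec) -> np.ndarray:
    """Viterbi decoding to per-bin behavior labels."""
    with np.errstate(divide="ignore"):
        loga = np.where(A > 0, np.log(np.maximum(A, 1e-300)), -np.inf)
        logpi = np.where(pi0 > 0, np.log(np.maximum(pi0, 1e-300)), -np.inf)
    logb = _emission_loglik(obs, params, spec.states)
    path = _viterbi(loga, logpi, logb)
    return np.array([spec.state_map[spec.states[i]] for i in path], dtype="<U8")


def classify_hmm(features_map: Mapping[str, pd.DataFrame],
                 config: SpeciesConfig, spec: Optional[HmmSpec] = None,
                 max_iter: int = 10) -> dict:
    """Fit the constrained HMM over all tracks jointly and decode each."""
    if spec is None:
        spec = HmmSpec.preset(config)
    keys = sorted(features_map.keys())
    obs_list = [bin_features(features_map[b], config, spec.bin_s) for b in keys]
    params, A, pi0, _ = fit_hmm(obs_list, spec, max_iter=max_iter)
    out = {}
    for bird, obs in zip(keys, obs_list):
        per_bin = decode(obs, params, A, pi0, spec)
        n = obs.attrs["n_seconds"]
        labels = np.repeat(per_bin, int(obs.attrs["bin_s"]))[:n]
        if labels.size < n:   # short final bin
            labels = np.concatenate([labels,
                                     np.repeat(per_bin[-1], n - labels.size)])
        out[bird] = make_ethogram(features_map[bird], labels, "HMM")
    return out
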