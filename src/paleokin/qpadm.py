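"""Admixture-weight estimation and model testing in the qpAdm style.

A target population's f4 profile against a set of "right" (reference)
populations is expressed as a convex combination of source populations'
profiles. Weights are fitted by generalized least squares under the
block-jackknife covariance of the f4 residuals, the full-model fit is
tested with a chi-square on the residuals, and each source's necessity
is tested by refitting with that source dropped (the nested rule).
Numerical equivalence with ADMIXTOOLS is not claimed; the validation
surface is parameter recovery on simulated admixture graphs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2

log = logging.getLogger(__name__)


@dataclass
class AdmixtureModel:
    target: str
    sources: tuple
    rights: tuple
    weights: np.ndarray | None = None
    se: np.ndarray | None = None
    p_value: float = float("nan")
    nested_p: list = field(default_factory=list)
    feasible: bool = False
    plausible: bool = False
    full_ok: bool = False          # full-model p >= 0.05
    nested_ok: bool = False        # every nested p < 0.05
    flags: list = field(default_factory=list)
    n_blocks: int = 0


# ---------------------------------------------------------------------------
# f4 building blocks
# ---------------------------------------------------------------------------

def _f4_sums(fw, fx, fy, fz, blocks, nb):
    """Per-block numerator sums and site counts of one f4 statistic."""
    num = (fw - fx) * (fy - fz)
    ok = np.isfinite(num)
    num_b = np.bincount(blocks[ok], weights=num[ok], minlength=nb)
    cnt_b = np.bincount(blocks[ok], minlength=nb).astype(float)
    return num_b, cnt_b


def _f4_full_loo(num_b, cnt_b):
    tot_n, tot_c = num_b.sum(), cnt_b.sum()
    if tot_c == 0:
        raise ValueError("f4 statistic has no overlapping sites")
    full = tot_n / tot_c
    denom = np.maximum(tot_c - cnt_b, 1.0)
    loo = (tot_n - num_b) / denom
    loo[tot_c - cnt_b == 0] = full
    return full, loo


def f4_matrix(left: Sequence[str], right: Sequence[str],
              freq_of: Mapping[str, np.ndarray], blocks: np.ndarray,
              allsnps: bool = True):
    """Matrix of f4(l0, l_i; r0, r_j) with block-jackknife covariance.

    With ``allsnps`` each entry uses its own four-population overlap;
    otherwise all entries are restricted to the common intersection.
    Returns ``(matrix, covariance, loo_matrices)`` where the matrix is
    (len(left)-1, len(right)-1) and the covariance is over its flattened
    entries.
    """
    if len(left) < 2 or len(right) < 2:
        raise ValueError("need >= 2 left and >= 2 right populations")
    for name in (*left, *right):
        f = freq_of.get(name)
        if f is None or not np.isfinite(f).any():
            raise ValueError(f"population {name!r} is empty after filters")
    nb = int(blocks.max()) + 1
    common = None
    if not allsnps:
        common = np.ones(len(blocks), dtype=bool)
        for name in (*left, *right):
            common &= np.isfinite(freq_of[name])
    l0, r0 = left[0], right[0]
    shape = (len(left) - 1, len(right) - 1)
    full = np.zeros(shape)
    loo = np.zeros((nb,) + shape)
    for i, li in enumerate(left[1:]):
        for j, rj in enumerate(right[1:]):
            fw, fx = freq_of[l0].copy(), freq_of[li].copy()
            fy, fz = freq_of[r0].copy(), freq_of[rj].copy()
            if common is not None:
                for arr in (fw, fx, fy, fz):
                    arr[~common] = np.nan
            nb_sums = _f4_sums(fw, fx, fy, fz, blocks, nb)
            full[i, j], loo[:, i, j] = _f4_full_loo(*nb_sums)
    flat = loo.reshape(nb, -1)
    mean = flat.mean(axis=0)
    cov = (nb - 1.0) / nb * (flat - mean).T @ (flat - mean)
    return full, cov, loo


# ---------------------------------------------------------------------------
# Weight fitting
# ---------------------------------------------------------------------------

def _jackknife_cov(loo: np.ndarray) -> np.ndarray:
    nb = loo.shape[0]
    mean = loo.mean(axis=0)
    return (nb - 1.0) / nb * (loo - mean).T @ (loo - mean)


def _regularize(omega: np.ndarray) -> tuple[np.ndarray, bool]:
    try:
        np.linalg.cholesky(omega)
        return omega, False
    except np.linalg.LinAlgError:
        scale = np.trace(omega) / omega.shape[0]
        eps = 1e-8 * (scale if scale > 0 else 1.0)
        reg = omega + eps * np.eye(omega.shape[0])
        log.info("ridge-regularized singular f4 covariance (eps=%.3g)", eps)
        try:
            np.linalg.cholesky(reg)
        except np.linalg.LinAlgError as e:
            raise ValueError("f4 covariance singular even after ridge") from e
        return reg, True


def fit_weights(target: str, sources: Sequence[str], rights: Sequence[str],
                freq_of: Mapping[str, np.ndarray], blocks: np.ndarray,
                allsnps: bool = True) -> AdmixtureModel:
    """Fit admixture weights for ``target`` from ``sources`` given rights.

    Weights sum to one by construction (the first source absorbs the
    affine constraint). The residual chi-square uses
    df = (|rights| - 1) - (|sources| - 1); the full-model p-value is its
    upper tail. Weight SEs come from refitting with each block deleted.
    """
    if len(rights) < len(sources) + 1:
        raise ValueError("need at least |sources|+1 right populations")
    s = len(sources)
    model = AdmixtureModel(target, tuple(sources), tuple(rights))
    # a_j = f4(t, s1; r0, rj); B[:, i] = f4(s_{i+1}, s1; r0, rj)
    lefts = [target, sources[0], *sources[1:]]
    mat, _, loo = f4_matrix(lefts, rights, freq_of, blocks, allsnps)
    a_full, a_loo = mat[0], loo[:, 0, :]                    # (J,), (nb, J)
    # f4(s_i, s1; r0, rj) = f4(t, s1; ...) - f4(t, s_i; ...)
    if s > 1:
        b_full = (a_full[None, :] - mat[1:]).T              # (J, S-1)
        b_loo = np.transpose(a_loo[:, None, :] - loo[:, 1:, :], (0, 2, 1))
    else:
        b_full = np.zeros((mat.shape[1], 0))
        b_loo = np.zeros((loo.shape[0], mat.shape[1], 0))
    nb = loo.shape[0]
    model.n_blocks = nb

    def solve(a_vec, b_mat, omega_inv):
        if b_mat.shape[1] == 0:
            return np.zeros(0)
        bt = b_mat.T @ omega_inv
        return np.linalg.solve(bt @ b_mat, bt @ a_vec)

    # stage 1: OLS residuals -> jackknife covariance of the residual vector
    w0 = (np.linalg.lstsq(b_full, a_full, rcond=None)[0]
          if s > 1 else np.zeros(0))
    e_loo = a_loo - np.einsum("bjk,k->bj", b_loo, w0)
    omega, _ = _regularize(_jackknife_cov(e_loo))
    omega_inv = np.linalg.inv(omega)
    # stage 2: GLS fit
    w_free = solve(a_full, b_full, omega_inv)
    resid = a_full - (b_full @ w_free if s > 1 else 0.0)
    q = float(resid @ omega_inv @ resid)
    df = (len(rights) - 1) - (s - 1)
    model.p_value = float(chi2.sf(q, df))
    weights = np.concatenate([[1.0 - w_free.sum()], w_free])
    model.weights = weights
    # jackknife SEs of the weights (refit per deleted block, fixed omega)
    if s > 1:
        w_loo = np.zeros((nb, s))
        for b in range(nb):
            wf = solve(a_loo[b], b_loo[b], omega_inv)
            w_loo[b] = np.concatenate([[1.0 - wf.sum()], wf])
        mean = w_loo.mean(axis=0)
        model.se = np.sqrt((nb - 1.0) / nb * ((w_loo - mean) ** 2).sum(axis=0))
    else:
        model.se = np.zeros(1)
    model.feasible = bool(np.all((weights >= -1e-9) & (weights <= 1 + 1e-9)))
    model.full_ok = model.p_value >= 0.05
    return model


def nested_rule(model: AdmixtureModel, freq_of: Mapping[str, np.ndarray],
                blocks: np.ndarray, allsnps: bool = True) -> AdmixtureModel:
    """Test every nested (one-source-dropped) model and decide plausibility.

    The full model is plausible iff (i) its own p >= 0.05, (ii) every
    nested model is rejected (p < 0.05), and (iii) the weights are
    feasible. The three conditions are reported separately.
    """
    model.nested_p = []
    for drop in range(len(model.sources)):
        reduced = [x for k, x in enumerate(model.sources) if k != drop]
        if not reduced:
            # the empty model explains nothing: trivially rejected
            model.nested_p.append(0.0)
            continue
        try:
            sub = fit_weights(model.target, reduced, model.rights,
                              freq_of, blocks, allsnps)
            model.nested_p.append(sub.p_value)
        except (ValueError, np.linalg.LinAlgError) as e:
            model.flags.append(f"nested fit failed dropping "
                               f"{model.sources[drop]}: {e}")
            model.nested_p.append(float("nan"))
    ps = np.array(model.nested_p)
    if np.isnan(ps).any():
        model.flags.append("undecidable: nested fit failure")
        model.plausible = False
        model.nested_ok = False
    else:
        model.nested_ok = bool((ps < 0.05).all())
        model.plausible = model.full_ok and model.nested_ok and model.feasible
    return model


def rotate_outgroups(target: str, pool: Sequence[str], k_sources: int,
                     freq_of: Mapping[str, np.ndarray], blocks: np.ndarray,
                     min_rights: int = 3, allsnps: bool = True,
                     max_models: int = 200,
                     single_individual_pops: set | None = None
                     ) -> list[AdmixtureModel]:
    """Fit every k-subset of the pool as sources, the complement as rights.

    Models are ranked by plausibility, then by full-model p. Source sets
    containing single-individual populations are flagged (reported, but
    to be approached with caution). Refuses combinatorially explosive
    pools.
    """
    if len(pool) < k_sources + min_rights:
        raise ValueError("pool too small for the requested sources + rights")
    combos = list(itertools.combinations(pool, k_sources))
    if len(combos) > max_models:
        raise ValueError(
            f"{len(combos)} candidate models exceed the guard of "
            f"{max_models}; shrink the pool or raise max_models explicitly")
    out = []
    for sources in combos:
        rights = [p for p in pool if p not in sources]
        try:
            m = fit_weights(target, sources, rights, freq_of, blocks, allsnps)
            nested_rule(m, freq_of, blocks, allsnps)
        except (ValueError, np.linalg.LinAlgError) as e:
            m = AdmixtureModel(target, tuple(sources), tuple(rights),
                               flags=[f"fit failed: {e}"])
        if single_individual_pops and set(sources) & single_individual_pops:
            m.flags.append("single-individual source")
        out.append(m)
    out.sort(key=lambda m: (not m.plausible,
                            -(m.p_value if np.isfinite(m.p_value) else -1)))
    return out


def per_individual_ancestry(target: str, source_trio: Sequence[str],
                            rights: Sequence[str], focal: str,
                            freq_of: Mapping[str, np.ndarray],
                            blocks: np.ndarray, allsnps: bool = True):
    """Three-way ancestry decomposition with the two-way fallback rule.

    Fit the three-way model; if some nested model is *not* rejected
    (nested p > 0.05), refit the corresponding two-way model without the
    unneeded source. If the surviving model lacks the focal source, the
    focal ancestry is 0. Returns ``(weights_by_source, model, provenance)``.
    """
    if focal not in source_trio:
        raise ValueError("focal source must be part of the trio")
    try:
        m3 = fit_weights(target, source_trio, rights, freq_of, blocks, allsnps)
        nested_rule(m3, freq_of, blocks, allsnps)
    except (ValueError, np.linalg.LinAlgError) as e:
        return None, None, f"all models failed: {e}"
    ps = np.array(m3.nested_p)
    if not np.isnan(ps).any() and (ps < 0.05).all():
        weights = dict(zip(m3.sources, m3.weights))
        return weights, m3, "three_way"
    # the source whose removal is NOT rejected is dispensable; drop the
    # one with the largest nested p
    drop = int(np.nanargmax(ps))
    reduced = [s for k, s in enumerate(source_trio) if k != drop]
    try:
        m2 = fit_weights(target, reduced, rights, freq_of, blocks, allsnps)
    except (ValueError, np.linalg.LinAlgError) as e:
        return None, None, f"two-way fallback failed: {e}"
    weights = {s: 0.0 for s in source_trio}
    weights.update(dict(zip(m2.sources, m2.weights)))
    prov = (f"two_way_fallback(dropped={source_trio[drop]})"
            + ("; focal_absent->0" if focal not in reduced else ""))
    return weights, m2, prov
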