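"""Beta-mixture modeling of CpG methylation and expression pairing.

Each CpG's tumor beta values are decomposed into 1–3 beta mixture
components by EM; model order is chosen by BIC.  Differential-methylation
(DM) values — component mean minus the mean beta of normal samples —
classify components as hypo- or hypermethylated, and a probe whose fit
contains both abnormal directions is *dual*-methylated (hypomethylated in
some patients' tumors, hypermethylated in others').  Finally, probes with
an abnormal component are tested for association between the mixture
grouping of the tumor samples and the expression of the gene(s) the probe
maps to; pairs passing FDR control are the *functional CpG–gene pairs*.

The mixture is fitted on tumor samples only; normal samples serve as the
methylation reference, mirroring the disease/control asymmetry of the
design.  The M-step uses a method-of-moments update as a fast proposal
and accepts it only if it does not decrease the EM objective, refining
numerically otherwise — so the observed-data log-likelihood is
non-decreasing at every iteration by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .io import AlignedCohort, BETA_EPS

logger = logging.getLogger(__name__)

STATE_HYPO = "Hypo"
STATE_HYPER = "Hyper"
STATE_DUAL = "Dual"
STATE_NONE = "None"

_MU_LIM = (1e-3, 1.0 - 1e-3)
_PHI_LIM = (1.01, 1e6)
_TOL = 1e-6
_MAX_ITER = 500
_PRUNE_WEIGHT = 0.01


@dataclass
class BetaMixtureFit:
    """A fitted beta mixture for one CpG plus (optionally) its state calls."""

    probe_id: str
    k: int
    weights: np.ndarray          # mixing proportions, sum to 1
    means: np.ndarray            # component means mu_k in (0,1)
    precisions: np.ndarray       # phi_k; alpha=mu*phi, beta=(1-mu)*phi
    log_likelihood: float
    bic: float
    loglik_trajectory: np.ndarray
    responsibilities: np.ndarray  # n x K
    sample_ids: tuple[str, ...] | None = None
    # set by call_states
    normal_mean: float | None = None
    dm: np.ndarray | None = None
    component_states: tuple[str, ...] | None = None
    probe_state: str | None = None

    @property
    def assignments(self) -> np.ndarray:
        """Hard component assignment (argmax responsibility) per sample."""
        return np.argmax(self.responsibilities, axis=1)

    def samples_in_states(self, states: set[str]) -> list[str]:
        if self.component_states is None or self.sample_ids is None:
            raise ValueError("state calls or sample ids missing")
        comp_ok = [i for i, s in enumerate(self.component_states) if s in states]
        assign = self.assignments
        return [sid for sid, a in zip(self.sample_ids, assign) if a in comp_ok]


def _beta_logpdf(x: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """log Beta(x; mu*phi, (1-mu)*phi), broadcasting x (n,1) against (K,)."""
    a = mu * phi
    b = (1.0 - mu) * phi
    return (gammaln(a + b) - gammaln(a) - gammaln(b)
            + (a - 1.0) * np.log(x) + (b - 1.0) * np.log1p(-x))


def _component_q(stats3: tuple[float, float, float], mu: float, phi: float) -> float:
    """Responsibility-weighted log-likelihood of one beta component.

    Depends on the data only through the sufficient statistics
    ``stats3 = (S1, S2, R) = (Σ r·log x, Σ r·log(1−x), Σ r)``, so every
    evaluation is O(1).
    """
    s1, s2, r = stats3
    a = mu * phi
    b = (1.0 - mu) * phi
    return ((a - 1.0) * s1 + (b - 1.0) * s2
            + r * (gammaln(a + b) - gammaln(a) - gammaln(b)))


def _moments_to_params(m1: float, var: float) -> tuple[float, float]:
    mu = float(np.clip(m1, *_MU_LIM))
    if var <= 0:
        phi = _PHI_LIM[1]
    else:
        phi = mu * (1.0 - mu) / var - 1.0
    return mu, float(np.clip(phi, *_PHI_LIM))


def _maximize_component(stats3, mu0, phi0) -> tuple[float, float]:
    """Safeguarded Newton ascent of the weighted beta log-likelihood in
    (log alpha, log beta); each step is O(1) via the sufficient stats."""
    from scipy.special import polygamma, digamma
    s1, s2, r = stats3
    a = mu0 * phi0
    b = (1.0 - mu0) * phi0
    q = _component_q(stats3, mu0, phi0)
    for _ in range(50):
        common = digamma(a + b)
        ga = s1 + r * (common - digamma(a))
        gb = s2 + r * (common - digamma(b))
        # gradient wrt (log a, log b)
        gla, glb = ga * a, gb * b
        tri = polygamma(1, a + b)
        haa = r * (tri - polygamma(1, a)) * a * a + gla
        hbb = r * (tri - polygamma(1, b)) * b * b + glb
        hab = r * tri * a * b
        det = haa * hbb - hab * hab
        if det == 0 or not np.isfinite(det):
            break
        da = -(hbb * gla - hab * glb) / det
        db = -(haa * glb - hab * gla) / det
        if not (np.isfinite(da) and np.isfinite(db)):
            break
        da = min(max(da, -10.0), 10.0)  # trust region in log space
        db = min(max(db, -10.0), 10.0)
        step = 1.0
        improved = False
        for _ in range(20):  # backtrack until the objective improves
            a_new = float(np.clip(a * np.exp(step * da), 1e-6, 1e7))
            b_new = float(np.clip(b * np.exp(step * db), 1e-6, 1e7))
            phi_new = a_new + b_new
            mu_new = a_new / phi_new
            q_new = _component_q(stats3, mu_new, phi_new)
            if q_new > q:
                a, b, q = a_new, b_new, q_new
                improved = True
                break
            step *= 0.5
        if not improved or abs(gla) + abs(glb) < 1e-10:
            break
    phi = float(np.clip(a + b, *_PHI_LIM))
    mu = float(np.clip(a / (a + b), *_MU_LIM))
    return mu, phi


def _batch_em(X: np.ndarray, W: np.ndarray, k: int):
    """Batched EM over P probes for a fixed component count.

    ``X`` is (P, n) with padded entries anywhere ``W`` (the 0/1 mask) is
    zero.  The E-step runs for all probes at once; the M-step is exact
    for the mixing weights and uses the method-of-moments proposal for
    each component's (mean, precision), accepted elementwise only when it
    does not decrease that component's weighted log-likelihood — so the
    per-probe observed log-likelihood is non-decreasing by construction.
    At convergence every component is polished by a safeguarded Newton
    ascent (which can only increase the objective further).

    Returns (weights, means, phis, resp, ll, trajectories).
    """
    P, n = X.shape
    n_eff = W.sum(axis=1)
    LX = np.log(X)
    L1X = np.log1p(-X)

    means = np.empty((P, k))
    phis = np.empty((P, k))
    # init: quantile partition of each probe's sorted non-missing values
    for p in range(P):
        vals = np.sort(X[p][W[p] > 0])
        for j, blk in enumerate(np.array_split(vals, k)):
            m1 = float(np.mean(blk))
            var = max(float(np.var(blk)) if len(blk) > 1 else 1e-4, 1e-6)
            means[p, j], phis[p, j] = _moments_to_params(m1, var)
    weights = np.full((P, k), 1.0 / k)

    trajectories: list[list[float]] = [[] for _ in range(P)]
    prev_ll = np.full(P, -np.inf)
    active = np.ones(P, dtype=bool)
    resp = np.zeros((P, n, k))
    ll = np.full(P, -np.inf)

    def e_step(sub):
        a = means[sub] * phis[sub]            # (p, k)
        b = (1.0 - means[sub]) * phis[sub]
        log_comp = (gammaln(a + b) - gammaln(a) - gammaln(b)
                    + np.log(weights[sub]))[:, None, :] \
            + (a[:, None, :] - 1.0) * LX[sub][:, :, None] \
            + (b[:, None, :] - 1.0) * L1X[sub][:, :, None]
        m = log_comp.max(axis=2, keepdims=True)
        log_norm = m[:, :, 0] + np.log(np.exp(log_comp - m).sum(axis=2))
        return (np.exp(log_comp - log_norm[:, :, None]),
                (log_norm * W[sub]).sum(axis=1))

    for _ in range(_MAX_ITER):
        sub = np.nonzero(active)[0]
        new_resp, new_ll = e_step(sub)
        resp[sub] = new_resp
        ll[sub] = new_ll
        for p in sub:
            trajectories[p].append(float(ll[p]))
        progressed = ll[sub] - prev_ll[sub] >= _TOL
        prev_ll[sub] = ll[sub]
        active[sub] = progressed
        if not active.any():
            break
        sub = sub[progressed]
        rw = resp[sub] * W[sub][:, :, None]   # masked responsibilities
        nk = rw.sum(axis=1)                   # (p, k)
        new_weights = np.clip(nk, 1e-12, None)
        new_weights /= new_weights.sum(axis=1, keepdims=True)
        nk_safe = np.clip(nk, 1e-12, None)
        Xs = X[sub]
        m1 = (rw * Xs[:, :, None]).sum(axis=1) / nk_safe
        m2 = (rw * (Xs * Xs)[:, :, None]).sum(axis=1) / nk_safe
        var = np.clip(m2 - m1 * m1, 1e-12, None)
        mu_new = np.clip(m1, *_MU_LIM)
        phi_new = np.clip(mu_new * (1.0 - mu_new) / var - 1.0, *_PHI_LIM)
        s1 = (rw * LX[sub][:, :, None]).sum(axis=1)
        s2 = (rw * L1X[sub][:, :, None]).sum(axis=1)

        def q_of(mu, phi):
            a = mu * phi
            b = (1.0 - mu) * phi
            return ((a - 1.0) * s1 + (b - 1.0) * s2
                    + nk * (gammaln(a + b) - gammaln(a) - gammaln(b)))

        accept = q_of(mu_new, phi_new) >= q_of(means[sub], phis[sub])
        means[sub] = np.where(accept, mu_new, means[sub])
        phis[sub] = np.where(accept, phi_new, phis[sub])
        weights[sub] = new_weights

    # Newton polish of every component, then one final E-step; both steps
    # can only increase the observed log-likelihood
    rw = resp * W[:, :, None]
    nk = rw.sum(axis=1)
    s1 = (rw * LX[:, :, None]).sum(axis=1)
    s2 = (rw * L1X[:, :, None]).sum(axis=1)
    for p in range(P):
        for j in range(k):
            if nk[p, j] <= 1e-9:
                continue
            stats3 = (float(s1[p, j]), float(s2[p, j]), float(nk[p, j]))
            mu_opt, phi_opt = _maximize_component(stats3, means[p, j], phis[p, j])
            if (_component_q(stats3, mu_opt, phi_opt)
                    >= _component_q(stats3, means[p, j], phis[p, j])):
                means[p, j], phis[p, j] = mu_opt, phi_opt
    resp, ll = e_step(np.arange(P))
    for p in range(P):
        if trajectories[p] and ll[p] >= trajectories[p][-1]:
            trajectories[p].append(float(ll[p]))
    return weights, means, phis, resp, ll, trajectories


def _fit_batch(X: np.ndarray, W: np.ndarray, k_max: int):
    """BIC-selected fits for every probe row; returns per-probe tuples
    (k, weights, means, phis, resp, ll, traj, bic)."""
    P, n = X.shape
    n_eff = W.sum(axis=1)
    best = [None] * P
    for k in range(1, k_max + 1):
        idx = np.arange(P)
        Xk, Wk, kk = X, W, k
        results = [None] * P
        while len(idx):
            weights, means, phis, resp, ll, trajs = _batch_em(Xk, Wk, kk)
            if kk > 1:
                degenerate = (weights < _PRUNE_WEIGHT).any(axis=1)
            else:
                degenerate = np.zeros(len(idx), dtype=bool)
            for row, p in enumerate(idx):
                if not degenerate[row]:
                    results[p] = (kk, weights[row], means[row], phis[row],
                                  resp[row], float(ll[row]), trajs[row])
            keep = degenerate
            idx = idx[keep]
            Xk, Wk = Xk[keep], Wk[keep]
            kk -= 1  # degenerate component: prune, refit the subset smaller
        for p in range(P):
            kk_p, weights, means, phis, resp, ll, traj = results[p]
            bic = -2.0 * ll + (3 * kk_p - 1) * np.log(n_eff[p])
            if best[p] is None or bic < best[p][-1]:
                best[p] = (kk_p, weights, means, phis, resp, ll, traj, bic)
    return best


def fit_beta_mixture(tumor_betas: np.ndarray, probe_id: str = "",
                     k_max: int = 3, seed: int = 0,
                     sample_ids=None) -> BetaMixtureFit:
    """Fit beta mixtures with K = 1..k_max and select K by minimum BIC.

    BIC = −2ℓ + (3K−1)·ln n (K−1 free weights plus mean and precision per
    component).  Components whose converged weight falls below 1% are
    pruned and the model is refitted with K−1.  The quantile-partition
    initialization is deterministic; ``seed`` is accepted for interface
    stability and reserved for randomized restarts.
    """
    x = np.asarray(tumor_betas, dtype=float)
    keep = np.isfinite(x)
    x = x[keep]
    if len(x) < 10:
        raise ValueError(f"probe {probe_id!r}: need ≥10 non-missing tumor betas, "
                         f"got {len(x)}")
    if sample_ids is not None:
        sample_ids = [s for s, m in zip(sample_ids, keep) if m]
    x = np.clip(x, BETA_EPS, 1.0 - BETA_EPS)
    k, weights, means, phis, resp, ll, traj, bic = _fit_batch(
        x[None, :], np.ones((1, len(x))), k_max)[0]
    return BetaMixtureFit(
        probe_id=probe_id, k=k, weights=weights[:k], means=means[:k],
        precisions=phis[:k], log_likelihood=ll, bic=bic,
        loglik_trajectory=np.asarray(traj), responsibilities=resp[:, :k],
        sample_ids=tuple(sample_ids) if sample_ids is not None else None,
    )


def call_states(fit: BetaMixtureFit, normal_betas: np.ndarray,
                dm_min: float = 0.10, min_normal: int = 5) -> BetaMixtureFit:
    """Compute DM values against the normal reference and call states.

    A component is hypomethylated when its DM value (component mean minus
    normal mean) is ≤ −dm_min, hypermethylated when ≥ +dm_min, otherwise
    normal-like.  The probe summary is Hypo / Hyper / Dual (both abnormal
    directions present) / None.
    """
    nb = np.asarray(normal_betas, dtype=float)
    nb = nb[np.isfinite(nb)]
    if len(nb) < min_normal:
        raise ValueError(f"probe {fit.probe_id!r}: need ≥{min_normal} normal betas")
    fit.normal_mean = float(np.mean(nb))
    fit.dm = fit.means - fit.normal_mean
    states = []
    for d in fit.dm:
        if d <= -dm_min:
            states.append("hypo")
        elif d >= dm_min:
            states.append("hyper")
        else:
            states.append("normal-like")
    fit.component_states = tuple(states)
    has_hypo = "hypo" in states
    has_hyper = "hyper" in states
    if has_hypo and has_hyper:
        fit.probe_state = STATE_DUAL
    elif has_hypo:
        fit.probe_state = STATE_HYPO
    elif has_hyper:
        fit.probe_state = STATE_HYPER
    else:
        fit.probe_state = STATE_NONE
    return fit


def fit_cohort(meth: pd.DataFrame, cohort: AlignedCohort, k_max: int = 3,
               dm_min: float = 0.10, seed: int = 0) -> list[BetaMixtureFit]:
    """Fit and state-call every probe of a methylation matrix.

    All probes are fitted through the shared batched EM engine (one
    vectorized program per candidate K), which is numerically identical
    to per-probe :func:`fit_beta_mixture` calls but orders of magnitude
    faster on array-scale input.
    """
    tumor = list(cohort.tumor)
    normal = list(cohort.normal)
    tmat = meth.loc[:, tumor].to_numpy(dtype=float)
    mask = np.isfinite(tmat)
    usable = mask.sum(axis=1) >= 10
    n_skipped = int((~usable).sum())
    if n_skipped:
        logger.info("fit_cohort: skipped %d probes with <10 tumor values", n_skipped)
    probes = meth.index[usable]
    X = np.where(mask, np.clip(tmat, BETA_EPS, 1.0 - BETA_EPS), 0.5)[usable]
    W = mask[usable].astype(float)
    results = _fit_batch(X, W, k_max)
    fits = []
    for row, probe in enumerate(probes):
        k, weights, means, phis, resp, ll, traj, bic = results[row]
        keep = W[row] > 0
        sample_ids = tuple(s for s, m in zip(tumor, keep) if m)
        fit = BetaMixtureFit(
            probe_id=str(probe), k=k, weights=weights[:k], means=means[:k],
            precisions=phis[:k], log_likelihood=ll, bic=bic,
            loglik_trajectory=np.asarray(traj),
            responsibilities=resp[keep][:, :k], sample_ids=sample_ids)
        call_states(fit, meth.loc[probe, normal].to_numpy(dtype=float),
                    dm_min=dm_min)
        fits.append(fit)
    return fits


def pair_with_expression(fits: list[BetaMixtureFit], manifest: pd.DataFrame,
                         expr: pd.DataFrame, cohort: AlignedCohort,
                         assoc_fdr_max: float = 0.05,
                         promoter_only: bool = True,
                         min_group: int = 3) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Test CpG mixture grouping against mapped genes' tumor expression.

    For each probe with an abnormal component, samples assigned to
    abnormal component(s) are compared with samples assigned to
    normal-like component(s) — or with normal-tissue samples when no
    normal-like component exists — by a rank-sum test on the gene's
    expression.  BH correction runs across all tested pairs.

    Returns ``(functional_pairs, all_tested)``; the second frame is the
    full per-pair table before the FDR cut (the raw mixture-model output).
    """
    probe_rows = manifest
    if promoter_only:
        probe_rows = manifest[manifest["region_class"] == "promoter"]
    by_probe = {p: sub for p, sub in probe_rows.groupby("probe_id")}
    expr_genes = set(expr.index)
    records = []
    n_skipped = 0
    for fit in fits:
        if fit.probe_state not in (STATE_HYPO, STATE_HYPER, STATE_DUAL):
            continue
        sub = by_probe.get(fit.probe_id)
        if sub is None:
            continue
        abnormal = fit.samples_in_states({"hypo", "hyper"})
        reference = fit.samples_in_states({"normal-like"})
        against_normals = not reference
        if against_normals:
            reference = list(cohort.normal)
        dm_values = ",".join(f"{d:.4f}" for d, s in
                             zip(fit.dm, fit.component_states)
                             if s != "normal-like")
        for gene in sub["gene_symbol"]:
            if gene not in expr_genes:
                continue
            a = expr.loc[gene, abnormal].to_numpy(dtype=float)
            b = expr.loc[gene, reference].to_numpy(dtype=float)
            a, b = a[np.isfinite(a)], b[np.isfinite(b)]
            if len(a) < min_group or len(b) < min_group:
                n_skipped += 1
                continue
            if np.ptp(np.concatenate([a, b])) == 0:
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                             method="asymptotic").pvalue)
            records.append((fit.probe_id, gene, fit.probe_state, dm_values, p))
    if n_skipped:
        logger.info("pair_with_expression: skipped %d pairs with <%d samples "
                    "in a comparison group", n_skipped, min_group)
    tested = pd.DataFrame(records, columns=["probe_id", "gene_symbol",
                                            "cpg_state", "dm_values", "assoc_p"])
    if tested.empty:
        tested["assoc_fdr"] = pd.Series(dtype=float)
        return tested.copy(), tested
    tested["assoc_fdr"] = multipletests(tested["assoc_p"], method="fdr_bh")[1]
    functional = tested[tested["assoc_fdr"] <= assoc_fdr_max].reset_index(drop=True)
    return functional, tested


def fits_to_frame(fits: list[BetaMixtureFit]) -> pd.DataFrame:
    """Flatten fits into a table (one row per probe, components joined)."""
    rows = []
    for f in fits:
        rows.append({
            "probe_id": f.probe_id,
            "k": f.k,
            "weights": ",".join(f"{w:.4f}" for w in f.weights),
            "means": ",".join(f"{m:.4f}" for m in f.means),
            "precisions": ",".join(f"{p:.2f}" for p in f.precisions),
            "normal_mean": f.normal_mean,
            "dm_values": ",".join(f"{d:.4f}" for d in f.dm)
            if f.dm is not None else "",
            "component_states": ",".join(f.component_states)
            if f.component_states else "",
            "probe_state": f.probe_state,
            "bic": f.bic,
            "log_likelihood": f.log_likelihood,
        })
    return pd.DataFrame(rows)
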