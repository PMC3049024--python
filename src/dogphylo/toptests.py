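"""Maximum-likelihood topology tests over attachment-hypothesis sets.

Per-site log-likelihoods are computed at each hypothesis's optimized
branch lengths; the Shimodaira-Hasegawa (SH) test uses RELL resampling
(bootstrap over site columns without re-optimization, performed at the
site-pattern level with weights for speed), and the approximately
unbiased (AU) test fits the signed-distance/curvature model to bootstrap
proportions over a grid of resampling scales.  A correlation diagnostic
compares log10 Bayes factors with SH likelihood differences across the
same hypotheses.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from ._engine import PatternTable, TreeLikelihood
from .models import RateModel, SubstitutionModel

P_FLOOR_DEFAULT = 1e-5


@dataclass
class SiteLnLMatrix:
    """Hypotheses x site-patterns log-likelihoods with pattern weights."""

    hyp_ids: list[str]
    matrix: np.ndarray  # (n_hyps, n_patterns)
    weights: np.ndarray  # pattern multiplicities
    site_to_pattern: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.site_to_pattern)

    def totals(self) -> np.ndarray:
        return self.matrix @ self.weights

    def expanded(self) -> np.ndarray:
        """Per-site matrix on the full site grid."""
        return self.matrix[:, self.site_to_pattern]

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("hypothesis\t" + "\t".join(
                f"p{i}" for i in range(self.matrix.shape[1])) + "\n")
            fh.write("weight\t" + "\t".join(str(int(w)) for w in self.weights) + "\n")
            for h, row in zip(self.hyp_ids, self.matrix):
                fh.write(h + "\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")


@dataclass
class TopologyTestResult:
    table: pd.DataFrame  # hypothesis, lnl, delta, sh_p, au_p

    def write_tsv(self, path: str, p_floor: float = P_FLOOR_DEFAULT) -> None:
        out = self.table.copy()
        for col in ("sh_p", "au_p"):
            out[col] = out[col].map(
                lambda p: f"<{p_floor:g}" if p < p_floor else f"{p:.5f}"
            )
        out.to_csv(path, sep="\t", index=False)


def per_site_lnl(
    hypotheses: list[tuple[str, dendropy.Tree]],
    patterns: PatternTable,
    model: SubstitutionModel,
    rates: RateModel,
    optimize_shape: bool = False,
    condition_observable: bool = False,
    opt_tol: float = 1e-5,
) -> SiteLnLMatrix:
    """Optimize each hypothesis, then record per-pattern log-likelihoods."""
    rows = []
    ids = []
    for hid, tree in hypotheses:
        eng = TreeLikelihood(tree, patterns, model, rates, condition_observable)
        if optimize_shape:
            eng.optimize_shape_and_lengths(tol=max(opt_tol, 1e-4))
        else:
            eng.optimize_branch_lengths(tol=opt_tol)
        rows.append(eng.pattern_logliks())
        ids.append(hid)
    return SiteLnLMatrix(
        ids, np.vstack(rows), patterns.weights, patterns.site_to_pattern
    )


def sh_test(
    matrix: SiteLnLMatrix, n_rell: int = 1000, seed: int = 0
) -> np.ndarray:
    """SH test p-values by centred RELL resampling.

    Classic simultaneous construction: each hypothesis's resampled total
    is centred by its own mean over replicates; the null deviate for
    hypothesis h in replicate b is ``max_g S_gb - S_hb``, compared
    one-sidedly against the observed lnL deficit of h.  The
    maximum-likelihood hypothesis has p = 1 by construction.
    """
    if len(matrix.hyp_ids) < 2:
        raise ValueError("need at least two hypotheses")
    rng = np.random.default_rng(seed)
    totals = matrix.totals()
    delta = totals.max() - totals  # observed deficits, best = 0
    n = matrix.n_sites
    p = matrix.weights / matrix.weights.sum()
    reps = rng.multinomial(n, p, size=n_rell)  # (B, n_patterns)
    boot = reps @ matrix.matrix.T  # (B, n_hyps)
    centred = boot - boot.mean(axis=0, keepdims=True)
    null_dev = centred.max(axis=1, keepdims=True) - centred  # (B, n_hyps)
    return np.array(
        [np.mean(null_dev[:, h] >= d) for h, d in enumerate(delta)]
    )


def au_test(
    matrix: SiteLnLMatrix,
    scales: np.ndarray | None = None,
    n_boot_per_scale: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """AU test via multiscale bootstrap; returns (p-values, degenerate flags).

    For each scale r the resample size is round(r * n_sites); z(BP) is fit
    as d*sqrt(r) + c/sqrt(r) by weighted least squares and
    p = 1 - Phi(d - c).  Hypotheses that win (or lose) every replicate at
    every scale are clamped to p = 1 (or 0) and flagged.
    """
    scales = np.asarray(
        scales if scales is not None else np.arange(0.5, 1.45, 0.1)
    )
    rng = np.random.default_rng(seed)
    H = len(matrix.hyp_ids)
    n = matrix.n_sites
    p = matrix.weights / matrix.weights.sum()
    bp = np.zeros((len(scales), H))
    for si, r in enumerate(scales):
        m = max(int(round(r * n)), 1)
        reps = rng.multinomial(m, p, size=n_boot_per_scale)
        boot = reps @ matrix.matrix.T
        best = np.argmax(boot, axis=1)
        for h in range(H):
            bp[si, h] = np.mean(best == h)
    pvals = np.empty(H)
    degenerate = np.zeros(H, dtype=bool)
    B = n_boot_per_scale
    eps = 1.0 / (2.0 * B)
    for h in range(H):
        col = bp[:, h]
        if np.all(col >= 1.0):
            pvals[h] = 1.0
            degenerate[h] = True
            continue
        if np.all(col <= 0.0):
            pvals[h] = 0.0
            degenerate[h] = True
            continue
        cl = np.clip(col, eps, 1.0 - eps)
        z = stats.norm.ppf(1.0 - cl)
        sr = np.sqrt(scales)
        X = np.column_stack([sr, 1.0 / sr])
        phi = stats.norm.pdf(z)
        wls = B * phi**2 / (cl * (1.0 - cl))
        W = np.sqrt(wls)
        coef, *_ = np.linalg.lstsq(X * W[:, None], z * W, rcond=None)
        d, c = coef
        pvals[h] = float(1.0 - stats.norm.cdf(d - c))
    return pvals, degenerate


def run_topology_tests(
    hypotheses: list[tuple[str, dendropy.Tree]],
    patterns: PatternTable,
    model: SubstitutionModel,
    rates: RateModel,
    n_rell: int = 1000,
    seed: int = 0,
    **kwargs,
) -> tuple[TopologyTestResult, SiteLnLMatrix]:
    mat = per_site_lnl(hypotheses, patterns, model, rates, **kwargs)
    totals = mat.totals()
    delta = totals.max() - totals
    sh = sh_test(mat, n_rell=n_rell, seed=seed)
    au, degen = au_test(mat, n_boot_per_scale=n_rell, seed=seed + 1)
    df = pd.DataFrame(
        {
            "hypothesis": mat.hyp_ids,
            "lnl": totals,
            "delta": delta,
            "sh_p": sh,
            "au_p": au,
            "au_degenerate": degen,
        }
    )
    return TopologyTestResult(df), mat


def compare_bf_likelihood(
    bf: dict[str, float], delta: dict[str, float]
) -> tuple[float, float, pd.DataFrame]:
    """OLS r^2 (and p) between average log10 BFs and SH lnL differences."""
    common = sorted(set(bf) & set(delta))
    if len(common) < 3:
        raise ValueError("need at least 3 shared hypotheses")
    x = np.array([bf[h] for h in common])
    y = np.array([delta[h] for h in common])
    res = stats.linregress(x, y)
    df = pd.DataFrame({"hypothesis": common, "log10_bf": x, "delta_lnl": y})
    return float(res.rvalue**2), float(max(res.pvalue, P_FLOOR_DEFAULT)), df
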