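"""eQTL detection with a permutation null, and the polygenic risk score.

Per gene-variant pair the model is simple linear regression of
inverse-normal-transformed expression on effective allele copy number
(dosage 0/1/2):

    y_i = alpha + beta * x_i + eps_i,   eps_i ~ N(0, sigma^2)

with significance from a Wald test on the OLS estimator of beta (t
distribution, n - 2 df). A variant is *cis* to a gene when it lies within
±1 Mb of the gene's coordinate span (closed interval, 1-based positions);
all other pairs are *trans*. The null distribution of the Wald p-values is
estimated empirically by permuting the expression sample identifiers
(jointly across genes, preserving gene-gene correlation); three permutation
rounds are the default.

The polygenic risk score is the coefficient-weighted sum of effect-allele
dosages over a fixed SNP panel, restricted to the panel variants actually
genotyped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata
from scipy.stats import t as t_dist

logger = logging.getLogger(__name__)

__all__ = [
    "inverse_normal",
    "fit_eqtl",
    "PermutationNull",
    "permutation_null",
    "PrsModel",
    "prs_score",
]

EQTL_COLUMNS = ("gene", "variant", "beta_hat", "se", "wald_p", "cis",
                "intercept", "sigma2")


def inverse_normal(values, c: float = 0.375) -> np.ndarray:
    """Rank-based inverse normal transform with Blom offset c = 3/8.

    Maps value ranks to Phi^-1((rank - c) / (n + 1 - 2c)); ties receive
    the average rank. Invariant under monotone transformations of the
    input. All-identical input is rejected (ranks carry no information).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("inverse_normal requires >=3 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("inverse_normal requires finite values")
    if np.all(x == x[0]):
        raise ValueError("all values identical; rank transform undefined")
    ranks = rankdata(x, method="average")
    return ndtri((ranks - c) / (x.size + 1 - 2 * c))


def _cis_mask(gene_index, variant_index, gene_coords, variant_coords, window):
    """Boolean matrix (genes x variants): variant within ±window of the gene span."""
    gc = gene_coords.loc[gene_index]
    vc = variant_coords.loc[variant_index]
    same_chrom = (gc["chrom"].to_numpy()[:, None] == vc["chrom"].to_numpy()[None, :])
    start = gc["start"].to_numpy(dtype=float)[:, None] - window
    end = gc["end"].to_numpy(dtype=float)[:, None] + window
    pos = vc["pos"].to_numpy(dtype=float)[None, :]
    return same_chrom & (pos >= start) & (pos <= end)


def fit_eqtl(
    expression: pd.DataFrame,
    genotypes: pd.DataFrame,
    gene_coords: pd.DataFrame | None = None,
    variant_coords: pd.DataFrame | None = None,
    cis_window: int = 1_000_000,
    transform: bool = True,
    pairs: str = "all",
) -> pd.DataFrame:
    """OLS + Wald test for every gene-variant pair, fully vectorized.

    Parameters
    ----------
    expression
        Genes x samples matrix.
    genotypes
        Variants x samples dosage matrix with values in [0, 2]. Samples are
        matched to the expression matrix by label; >=10 shared samples are
        required. Monomorphic variants are skipped with a logged count.
    gene_coords, variant_coords
        Optional coordinate tables (``chrom``/``start``/``end`` for genes,
        ``chrom``/``pos`` for variants) used to flag cis pairs. Without
        them every pair is reported with ``cis=False``.
    cis_window
        Half-width of the cis window in bases (default ±1 Mb).
    transform
        Apply the rank-based inverse normal transform per gene (default).
        ``False`` fits on the raw scale (useful for effect-size checks).
    pairs
        ``"all"`` or ``"cis"`` (restrict output to cis pairs; requires
        coordinates).

    Returns
    -------
    DataFrame with one row per tested pair: gene, variant, beta_hat, se,
    wald_p, cis, intercept, sigma2.
    """
    shared = expression.columns.intersection(genotypes.columns)
    if len(shared) < 10:
        raise ValueError(f"need >=10 shared samples, found {len(shared)}")
    y = expression.loc[:, shared].to_numpy(dtype=float)
    x = genotypes.loc[:, shared].to_numpy(dtype=float)
    if np.nanmin(x) < 0 or np.nanmax(x) > 2:
        raise ValueError("dosages must lie in [0, 2]")
    n = len(shared)

    poly = x.std(axis=1) > 0
    n_mono = int((~poly).sum())
    if n_mono:
        logger.warning("skipping %d monomorphic variant(s)", n_mono)
    x = x[poly]
    variants = genotypes.index[poly]
    genes = expression.index

    if transform:
        y = np.apply_along_axis(inverse_normal, 1, y)

    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sxx = (xc ** 2).sum(axis=1)                      # (V,)
    sxy = yc @ xc.T                                  # (G, V)
    beta = sxy / sxx[None, :]
    syy = (yc ** 2).sum(axis=1)                      # (G,)
    rss = syy[:, None] - beta * sxy
    rss = np.clip(rss, 0.0, None)
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 / sxx[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * t_dist.sf(np.abs(tstat), df=n - 2)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    intercept = y.mean(axis=1)[:, None] - beta * x.mean(axis=1)[None, :]

    if gene_coords is not None and variant_coords is not None:
        cis = _cis_mask(genes, variants, gene_coords, variant_coords, cis_window)
    else:
        if pairs == "cis":
            raise ValueError("pairs='cis' requires gene and variant coordinates")
        cis = np.zeros((len(genes), len(variants)), dtype=bool)

    gi, vi = np.indices((len(genes), len(variants)))
    keep = cis.ravel() if pairs == "cis" else np.ones(gi.size, dtype=bool)
    out = pd.DataFrame({
        "gene": genes.to_numpy()[gi.ravel()[keep]],
        "variant": variants.to_numpy()[vi.ravel()[keep]],
        "beta_hat": beta.ravel()[keep],
        "se": se.ravel()[keep],
        "wald_p": p.ravel()[keep],
        "cis": cis.ravel()[keep],
        "intercept": intercept.ravel()[keep],
        "sigma2": sigma2.ravel()[keep],
    })
    return out


@dataclass
class PermutationNull:
    """Observed and permutation-null Wald p-values with an empirical-FDR map."""

    observed_p: np.ndarray
    null_p: np.ndarray
    n_rounds: int

    def fdr(self, threshold: float) -> float:
        """Empirical FDR at a p-value threshold.

        (mean per-round null count <= t) / (observed count <= t); infinite
        when nothing is observed below the threshold.
        """
        observed = int((self.observed_p <= threshold).sum())
        null_mean = (self.null_p <= threshold).sum() / self.n_rounds
        if observed == 0:
            return float("inf")
        return float(min(null_mean / observed, 1.0))


def permutation_null(
    expression: pd.DataFrame,
    genotypes: pd.DataFrame,
    n_rounds: int = 3,
    rng_seed: int = 0,
    **fit_kwargs,
) -> PermutationNull:
    """Empirical null for the eQTL scan by permuting expression sample identifiers.

    Each round relabels the expression matrix's sample identifiers with a
    random permutation — a single joint permutation across all genes, so
    gene-gene correlation is preserved — and reruns the full scan. The
    pooled null p-values and the observed p-values are returned together
    with an empirical-FDR function.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    rng = np.random.default_rng(rng_seed)
    observed = fit_eqtl(expression, genotypes, **fit_kwargs)["wald_p"].to_numpy()
    null_parts = []
    cols = expression.columns.to_numpy()
    for _ in range(n_rounds):
        perm = rng.permutation(len(cols))
        shuffled = pd.DataFrame(
            expression.to_numpy(), index=expression.index, columns=cols[perm]
        )
        null_parts.append(
            fit_eqtl(shuffled, genotypes, **fit_kwargs)["wald_p"].to_numpy()
        )
    return PermutationNull(
        observed_p=observed,
        null_p=np.concatenate(null_parts),
        n_rounds=n_rounds,
    )


@dataclass
class PrsModel:
    """A fixed panel of risk variants with effect alleles and coefficients."""

    entries: list  # of (variant_id, effect_allele, coefficient)

    def __post_init__(self):
        ids = [e[0] for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate variant ids in PRS model")
        if not all(np.isfinite(e[2]) for e in self.entries):
            raise ValueError("PRS coefficients must be finite")

    @property
    def variants(self) -> list:
        return [e[0] for e in self.entries]

    @property
    def coefficients(self) -> dict:
        return {e[0]: float(e[2]) for e in self.entries}


def prs_score(model: PrsModel, genotypes: pd.DataFrame) -> tuple[pd.Series, int]:
    """Polygenic risk score per sample.

    score_s = sum_j coefficient_j * dosage_js over the panel variants
    present in the genotype matrix (the panel is trimmed to the genotyped
    intersection). Returns (scores, number of variants used).
    """
    coef = model.coefficients
    present = [v for v in model.variants if v in genotypes.index]
    if not present:
        raise ValueError("no PRS model variant is present in the genotype matrix")
    if len(present) < len(model.variants):
        logger.warning("PRS panel trimmed to %d of %d variant(s) present in genotypes",
                       len(present), len(model.variants))
    weights = np.array([coef[v] for v in present])
    dosages = genotypes.loc[present].to_numpy(dtype=float)
    scores = pd.Series(weights @ dosages, index=genotypes.columns, name="prs")
    return scores, len(present)
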