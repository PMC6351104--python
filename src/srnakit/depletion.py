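"""Per-gene antisense 22G counting and depletion/enrichment calling.

Two calling modes mirror the two analyses small-RNA studies report:

* simple mode, one library per genotype — a gene is depleted when wild-type
  abundance is at least ``min_rpm`` (10 rpm) and the mutant shows at least
  ``min_fold`` (2-fold) depletion, boundary inclusive;
* replicate mode — a negative-binomial exact test integrates replicates
  per genotype; a gene is called when BH q < 0.05, FC < 1/2 (strict) and at
  least one wild-type replicate reaches 10 rpm.

The exact test conditions on the per-gene total: with a common moment-
matched dispersion, replicate sums are negative binomial, and the observed
wild-type/mutant split of the total is compared with its exact conditional
distribution (two-sided: the summed probability of splits no more likely
than the observed one).  Counts are scaled to a common (geometric-mean)
library size first.  This calibrated construction pins down type-I error
and power rather than any particular software's internals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .classify import AnnotationLookup
from .genome import GenomeBundle


def count_antisense_22g(hits: pd.DataFrame, bundle: GenomeBundle) -> pd.Series:
    """Sum the weights of 22G-class hits falling antisense within each gene.

    Multi-mapping reads contribute 1/n_hits per hit; hits outside genes or
    on the gene's own strand are ignored.  Returns a Series over all genes
    in the bundle (zeros included).
    """
    ann = AnnotationLookup(bundle)
    counts = {g.id: 0.0 for g in bundle.genes}
    sub = hits[hits["class"] == "22G"]
    for row in sub.itertuples(index=False):
        g = ann.genes.containing(row.chrom, row.start, row.start + row.length)
        if g is not None and g.strand != row.strand:
            counts[g.id] += row.weight
    out = pd.Series(counts, name="reads")
    out.index.name = "gene_id"
    return out


def _as_rpm_series(x) -> pd.Series:
    s = pd.Series(x, dtype=float)
    if (s < 0).any():
        raise ValueError("rpm values must be non-negative")
    return s


def call_depleted_simple(wt_rpm, mut_rpm, min_fold: float = 2.0,
                         min_rpm: float = 10.0) -> pd.DataFrame:
    """Single-library depletion rule, boundary inclusive.

    Called iff wt >= min_rpm and mut <= wt/min_fold.  Genes absent from one
    table are treated as 0 rpm there.
    """
    wt, mut = _as_rpm_series(wt_rpm), _as_rpm_series(mut_rpm)
    genes = wt.index.union(mut.index)
    wt = wt.reindex(genes, fill_value=0.0)
    mut = mut.reindex(genes, fill_value=0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mut / wt
    called = (wt >= min_rpm) & (mut <= wt / min_fold)
    return pd.DataFrame(
        {"wt_rpm": wt, "mut_rpm": mut, "fold_change": fc, "called": called}
    ).rename_axis("gene_id")


def call_enriched_ip(ip_rpm, input_rpm, min_fold: float = 2.0,
                     min_rpm: float = 10.0) -> pd.DataFrame:
    """IP-enrichment rule: ip >= min_fold * input and ip >= min_rpm.

    A zero-input gene counts as infinitely enriched once it clears the rpm
    floor.
    """
    ip, inp = _as_rpm_series(ip_rpm), _as_rpm_series(input_rpm)
    genes = ip.index.union(inp.index)
    ip = ip.reindex(genes, fill_value=0.0)
    inp = inp.reindex(genes, fill_value=0.0)
    called = (ip >= min_fold * inp) & (ip >= min_rpm)
    return pd.DataFrame(
        {"ip_rpm": ip, "input_rpm": inp, "called": called}
    ).rename_axis("gene_id")


# ------------------------------------------------------------ NB exact test


def estimate_common_dispersion(scaled: np.ndarray, groups: list[np.ndarray]) -> float:
    """Moment-matched common NB dispersion pooled across genes.

    Uses E[s^2 - m] = phi * mu^2 within each replicate group; the pooled
    ratio of summed excess variance to summed squared means is a consistent
    estimator even with few replicates per group.
    """
    num = 0.0
    den = 0.0
    for idx in groups:
        y = scaled[:, idx]
        if y.shape[1] < 2:
            continue
        m = y.mean(axis=1)
        v = y.var(axis=1, ddof=1)
        num += float(np.sum(v - m))
        den += float(np.sum(m * m))
    if den <= 0:
        return 0.0
    return max(num / den, 0.0)


def _log_conditional_split(t: int, size1: float, size2: float) -> np.ndarray:
    """log P(S1 = x | S1 + S2 = t) for x = 0..t, S_k ~ NB(size_k, p) iid in p.

    The NB success probability cancels in the conditional, which depends
    only on the shape (size) parameters.
    """
    x = np.arange(t + 1)
    lp = (
        gammaln(x + size1) - gammaln(x + 1)
        + gammaln(t - x + size2) - gammaln(t - x + 1)
    )
    return lp - logsumexp(lp)


def _log_binomial_split(t: int, pi1: float) -> np.ndarray:
    x = np.arange(t + 1)
    lp = (
        gammaln(t + 1) - gammaln(x + 1) - gammaln(t - x + 1)
        + x * np.log(pi1) + (t - x) * np.log1p(-pi1)
    )
    return lp - logsumexp(lp)


def nb_exact_test(wt: pd.DataFrame, mut: pd.DataFrame, lib_sizes=None) -> pd.DataFrame:
    """Two-sided exact conditional test of equal NB means, per gene.

    wt/mut are genes x replicates count tables sharing an index.  Returns a
    DataFrame with p, fold_change (normalized mutant/wild-type mean), and
    the scaled group means.  All-zero genes get p = 1 and missing FC.
    """
    if not wt.index.equals(mut.index):
        raise ValueError("wt and mut tables must share a gene index")
    n1, n2 = wt.shape[1], mut.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 replicates per group for dispersion estimation")
    counts = np.concatenate([wt.to_numpy(float), mut.to_numpy(float)], axis=1)
    if lib_sizes is None:
        sizes = counts.sum(axis=0)
    else:
        sizes = np.asarray(lib_sizes, dtype=float)
        if sizes.shape != (n1 + n2,):
            raise ValueError("lib_sizes must give one size per replicate (wt then mut)")
    if np.any(sizes <= 0):
        raise ValueError("library sizes must be positive")
    ref = float(np.exp(np.mean(np.log(sizes))))
    scaled = counts * (ref / sizes)

    phi = estimate_common_dispersion(scaled, [np.arange(n1), np.arange(n1, n1 + n2)])

    s1 = np.rint(scaled[:, :n1].sum(axis=1)).astype(int)
    s2 = np.rint(scaled[:, n1:].sum(axis=1)).astype(int)
    m1 = scaled[:, :n1].mean(axis=1)
    m2 = scaled[:, n1:].mean(axis=1)

    p = np.ones(len(s1))
    for i in range(len(s1)):
        t = s1[i] + s2[i]
        if t == 0:
            continue
        if phi > 0:
            lp = _log_conditional_split(t, n1 / phi, n2 / phi)
        else:
            lp = _log_binomial_split(t, n1 / (n1 + n2))
        obs = lp[s1[i]]
        p[i] = float(np.exp(logsumexp(lp[lp <= obs + 1e-10])))
    p = np.minimum(p, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        fc = m2 / m1
    fc = np.where((m1 == 0) & (m2 == 0), np.nan, fc)
    return pd.DataFrame(
        {"p": p, "fold_change": fc, "wt_mean": m1, "mut_mean": m2},
        index=wt.index,
    )


def call_depleted_replicates(wt: pd.DataFrame, mut: pd.DataFrame,
                             fdr: float = 0.05, max_fc: float = 0.5,
                             min_rpm: float = 10.0, lib_sizes=None) -> pd.DataFrame:
    """Replicate-mode depletion: q < fdr AND FC < max_fc AND the gene has at
    least min_rpm in at least one wild-type replicate.

    BH adjustment runs over the genes actually tested (nonzero total).
    """
    from .overlaps import bh_adjust

    res = nb_exact_test(wt, mut, lib_sizes=lib_sizes)
    n1 = wt.shape[1]
    if lib_sizes is None:
        wt_sizes = wt.to_numpy(float).sum(axis=0)
    else:
        wt_sizes = np.asarray(lib_sizes, dtype=float)[:n1]
    wt_rpm = 1e6 * wt.to_numpy(float) / wt_sizes
    res["wt_rpm_max"] = wt_rpm.max(axis=1)

    tested = (wt.sum(axis=1) + mut.sum(axis=1)) > 0
    q = np.full(len(res), np.nan)
    q[tested.to_numpy()] = bh_adjust(res.loc[tested, "p"].to_numpy())
    res["q"] = q
    res["called"] = (
        (res["q"] < fdr)
        & (res["fold_change"] < max_fc)
        & (res["wt_rpm_max"] >= min_rpm)
    ).fillna(False)
    return res
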