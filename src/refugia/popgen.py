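"""Summary statistics for diploid microsatellite data.

Per-population diversity (A, rarefied Ar, Ho, Nei's unbiased He, the
within-population inbreeding coefficient f), Weir & Cockerham's
variance-component F-statistics (FIS, FST, FIT), Slatkin's allele-size
based RST, permutation tests, and pairwise FST matrices.

All estimators drop missing genotypes per locus and population and use
count-weighted allele frequencies across unequal sample sizes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeDataset

__all__ = [
    "expected_heterozygosity",
    "observed_heterozygosity",
    "allelic_richness",
    "fstats_wc",
    "population_inbreeding",
    "rst_slatkin",
    "permutation_pvalue",
    "pairwise_fst_matrix",
    "mean_expected_heterozygosity",
    "summary_table",
]


# --------------------------------------------------------------------------- #
# single-population diversity


def _as_count_arrays(allele_counts) -> list[np.ndarray]:
    """Normalise per-locus allele counts to a list of 1-D count arrays."""
    out = []
    for c in allele_counts:
        if isinstance(c, dict):
            c = np.array(list(c.values()), dtype=float)
        else:
            c = np.asarray(c, dtype=float)
        out.append(c)
    return out


def expected_heterozygosity(allele_counts, unbiased: bool = True):
    """Gene diversity per locus from allele counts in one population.

    Uses Nei's unbiased estimator ``(C/(C-1)) * (1 - sum p^2)`` with ``C``
    gene copies (the convention of the standard F-statistics software);
    ``unbiased=False`` gives the plain ``1 - sum p^2``.  Loci with fewer
    than two gene copies are excluded with a warning.

    Returns ``(per_locus, mean)``.
    """
    per_locus = []
    for i, counts in enumerate(_as_count_arrays(allele_counts)):
        total = counts.sum()
        if total < 2:
            warnings.warn(f"locus {i}: fewer than two gene copies, excluded")
            continue
        p = counts / total
        he = 1.0 - (p**2).sum()
        if unbiased:
            he *= total / (total - 1.0)
        per_locus.append(he)
    per_locus = np.array(per_locus)
    return per_locus, (float(per_locus.mean()) if per_locus.size else float("nan"))


def observed_heterozygosity(alleles: np.ndarray) -> float:
    """Fraction of heterozygous genotypes, averaged over loci.

    ``alleles`` is an ``(n_individuals, n_loci, 2)`` slice for one
    population; missing genotypes are dropped per locus.
    """
    alleles = np.asarray(alleles)
    present = (alleles != MISSING).all(axis=2)
    het = alleles[:, :, 0] != alleles[:, :, 1]
    with np.errstate(invalid="ignore"):
        per_locus = np.where(
            present.sum(axis=0) > 0,
            (het & present).sum(axis=0) / np.maximum(present.sum(axis=0), 1),
            np.nan,
        )
    return float(np.nanmean(per_locus))


def _rarefied_allele_count(counts: np.ndarray, g: int) -> float:
    """E[# distinct alleles in a subsample of g gene copies] (rarefaction).

    ``sum_k 1 - C(C - N_k, g) / C(C, g)`` where ``C = sum N_k``; the ratio
    is computed as a running product so large counts stay exact.
    """
    c_tot = counts.sum()
    total = 0.0
    for n_k in counts:
        # C(C-Nk, g)/C(C, g) = prod_{i=0..g-1} (C-Nk-i)/(C-i)
        ratio = 1.0
        for i in range(g):
            num = c_tot - n_k - i
            if num <= 0:
                ratio = 0.0
                break
            ratio *= num / (c_tot - i)
        total += 1.0 - ratio
    return total


def allelic_richness(allele_counts, g: int = 4):
    """Rarefied allelic richness at a reference size of ``g`` gene copies.

    The default ``g=4`` corresponds to a reference sample of two diploid
    individuals.  Raises ``ValueError`` when any locus holds fewer than
    ``g`` copies (such populations are excluded from Ar columns upstream).

    Returns ``(per_locus, mean)``.
    """
    if g < 1:
        raise ValueError("g must be >= 1")
    per_locus = []
    for i, counts in enumerate(_as_count_arrays(allele_counts)):
        c_tot = counts.sum()
        if c_tot < g:
            raise ValueError(f"locus {i}: {int(c_tot)} gene copies < reference g={g}")
        per_locus.append(_rarefied_allele_count(counts, g))
    per_locus = np.array(per_locus)
    return per_locus, float(per_locus.mean())


# --------------------------------------------------------------------------- #
# Weir & Cockerham variance components


def _locus_components(dataset: GenotypeDataset, locus: int):
    """Per-allele variance components (a, b, c) at one locus.

    Follows the weighted analysis-of-variance estimator: for each allele,
    ``a`` is the among-population, ``b`` the among-individual-within-
    population and ``c`` the within-individual component.  Returns summed
    (a, b, c) over alleles, or ``None`` for unusable loci.
    """
    geno = dataset.alleles[:, locus, :]
    present = (geno != MISSING).all(axis=1)
    pops_here = dataset.pops[present]
    geno = geno[present]
    pop_codes, pop_idx = np.unique(pops_here, return_inverse=True)
    r = len(pop_codes)
    if r < 2:
        return None
    n_i = np.bincount(pop_idx, minlength=r).astype(float)
    if (n_i < 1).any():
        return None
    alleles, a_idx = np.unique(geno, return_inverse=True)
    k = len(alleles)
    if k < 2:
        return 0.0, 0.0, 0.0  # monomorphic: no variance at this locus
    a_idx = a_idx.reshape(geno.shape)
    # per-pop allele counts and heterozygote-for-allele counts
    counts = np.zeros((r, k))
    np.add.at(counts, (np.repeat(pop_idx, 2), a_idx.ravel()), 1.0)
    het = a_idx[:, 0] != a_idx[:, 1]
    het_counts = np.zeros((r, k))
    np.add.at(het_counts, (pop_idx[het], a_idx[het, 0]), 1.0)
    np.add.at(het_counts, (pop_idx[het], a_idx[het, 1]), 1.0)

    n_sum = n_i.sum()
    n_bar = n_sum / r
    n_c = (n_sum - (n_i**2).sum() / n_sum) / (r - 1.0)
    p_i = counts / (2.0 * n_i[:, None])
    p_bar = (n_i[:, None] * p_i).sum(axis=0) / n_sum
    s2 = (n_i[:, None] * (p_i - p_bar[None, :]) ** 2).sum(axis=0) / ((r - 1.0) * n_bar)
    h_bar = het_counts.sum(axis=0) / n_sum

    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1.0) / r * s2 - h_bar / 4.0) / (n_bar - 1.0)
    )
    b = (n_bar / (n_bar - 1.0)) * (
        p_bar * (1 - p_bar) - (r - 1.0) / r * s2 - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar
    )
    c = h_bar / 2.0
    return float(a.sum()), float(b.sum()), float(c.sum())


def fstats_wc(dataset: GenotypeDataset, per_locus: bool = False):
    """Weir-Cockerham FIS, FST and FIT from allele-frequency ANOVA.

    Variance components are summed over alleles and loci before taking
    ratios: ``FST = a/(a+b+c)``, ``FIT = (a+b)/(a+b+c)``, ``FIS = b/(b+c)``.
    Returns ``(FIS, FST, FIT)`` (NaN when every locus is monomorphic), or a
    DataFrame of per-locus estimates when ``per_locus`` is set.
    """
    if dataset.n_populations < 2:
        raise ValueError("F-statistics require at least two populations")
    comps = []
    for locus in range(dataset.n_loci):
        res = _locus_components(dataset, locus)
        comps.append(res if res is not None else (np.nan, np.nan, np.nan))
    comps = np.array(comps, dtype=float)
    if per_locus:
        with np.errstate(invalid="ignore", divide="ignore"):
            tot = comps.sum(axis=1)
            df = pd.DataFrame(
                {
                    "locus": dataset.locus_names,
                    "FIS": comps[:, 1] / (comps[:, 1] + comps[:, 2]),
                    "FST": comps[:, 0] / tot,
                    "FIT": (comps[:, 0] + comps[:, 1]) / tot,
                }
            )
        return df
    valid = ~np.isnan(comps).any(axis=1)
    a, b, c = comps[valid].sum(axis=0) if valid.any() else (np.nan, np.nan, np.nan)
    tot = a + b + c
    if not valid.any() or tot == 0.0:
        return float("nan"), float("nan"), float("nan")
    fis = b / (b + c) if (b + c) != 0.0 else float("nan")
    return fis, a / tot, (a + b) / tot


def population_inbreeding(dataset: GenotypeDataset, pop: int | str) -> float:
    """Within-population inbreeding coefficient f (single-population FIS).

    Uses the single-population reduction of the Weir-Cockerham components:
    ``b = n/(n-1) * (p(1-p) - (2n-1)/(4n) h)``, ``c = h/2``, summed over
    alleles and loci; ``f = b / (b + c)``.
    """
    rows = dataset.population_indices(pop)
    geno_all = dataset.alleles[rows]
    b_sum = c_sum = 0.0
    for locus in range(dataset.n_loci):
        geno = geno_all[:, locus, :]
        geno = geno[(geno != MISSING).all(axis=1)]
        n = geno.shape[0]
        if n < 2:
            continue
        alleles, a_idx = np.unique(geno, return_inverse=True)
        if len(alleles) < 2:
            continue
        a_idx = a_idx.reshape(geno.shape)
        counts = np.bincount(a_idx.ravel(), minlength=len(alleles)).astype(float)
        p = counts / (2.0 * n)
        het = a_idx[:, 0] != a_idx[:, 1]
        het_counts = np.zeros(len(alleles))
        np.add.at(het_counts, a_idx[het, 0], 1.0)
        np.add.at(het_counts, a_idx[het, 1], 1.0)
        h = het_counts / n
        b = (n / (n - 1.0)) * (p * (1 - p) - (2.0 * n - 1.0) / (4.0 * n) * h)
        c = h / 2.0
        b_sum += b.sum()
        c_sum += c.sum()
    if b_sum + c_sum == 0.0:
        return float("nan")
    return b_sum / (b_sum + c_sum)


# --------------------------------------------------------------------------- #
# Slatkin's RST


def _rst_sums(dataset: GenotypeDataset, locus: int):
    """(S_bar, S_w): mean squared allele-size differences, one locus.

    ``S_w`` averages, with equal population weights, the mean squared size
    difference over all pairs of gene copies within a population; ``S_bar``
    is the analogue over all pairs in the pooled sample.  Mean pair squared
    difference equals twice the unbiased variance.
    """
    geno = dataset.alleles[:, locus, :]
    present = (geno != MISSING).all(axis=1)
    pops_here = dataset.pops[present]
    sizes = geno[present].astype(float)
    pooled = sizes.ravel()
    if pooled.size < 2 or np.ptp(pooled) == 0:
        return np.nan, np.nan
    s_bar = 2.0 * pooled.var(ddof=1)
    s_within = []
    for code in np.unique(pops_here):
        x = sizes[pops_here == code].ravel()
        if x.size >= 2:
            s_within.append(2.0 * x.var(ddof=1))
    if not s_within:
        return np.nan, np.nan
    return s_bar, float(np.mean(s_within))


def rst_slatkin(dataset: GenotypeDataset, per_locus: bool = False):
    """Slatkin's RST from the variance in allele sizes.

    ``RST = (S_bar - S_w) / S_bar`` per locus; the multi-locus value is the
    ratio of the summed numerators to the summed denominators across loci.
    Monomorphic data yield NaN.
    """
    pairs = np.array([_rst_sums(dataset, l) for l in range(dataset.n_loci)])
    if per_locus:
        with np.errstate(invalid="ignore"):
            return pd.DataFrame(
                {
                    "locus": dataset.locus_names,
                    "RST": (pairs[:, 0] - pairs[:, 1]) / pairs[:, 0],
                }
            )
    valid = ~np.isnan(pairs).any(axis=1)
    if not valid.any():
        return float("nan")
    s_bar, s_w = pairs[valid].sum(axis=0)
    if s_bar == 0.0:
        return float("nan")
    return float((s_bar - s_w) / s_bar)


# --------------------------------------------------------------------------- #
# permutation tests


def _permute_fis(dataset: GenotypeDataset, rng: np.random.Generator) -> GenotypeDataset:
    """Shuffle gene copies among individuals within each population."""
    alleles = dataset.alleles.copy()
    for code in range(dataset.n_populations):
        rows = np.flatnonzero(dataset.pops == code)
        for locus in range(dataset.n_loci):
            block = alleles[rows, locus, :]
            present = (block != MISSING).all(axis=1)
            copies = block[present].ravel()
            rng.shuffle(copies)
            block[present] = copies.reshape(-1, 2)
            alleles[rows, locus, :] = block
    return GenotypeDataset(alleles=alleles, pops=dataset.pops, pop_names=list(dataset.pop_names))


def _permute_sizes(dataset: GenotypeDataset, rng: np.random.Generator) -> GenotypeDataset:
    """Reassign allele-size values among allelic states within each locus."""
    alleles = dataset.alleles.copy()
    for locus in range(dataset.n_loci):
        col = alleles[:, locus, :]
        states = np.unique(col[col != MISSING])
        shuffled = states.copy()
        rng.shuffle(shuffled)
        mapping = dict(zip(states.tolist(), shuffled.tolist()))
        mask = col != MISSING
        col[mask] = np.vectorize(mapping.__getitem__)(col[mask])
    return GenotypeDataset(alleles=alleles, pops=dataset.pops, pop_names=list(dataset.pop_names))


def permutation_pvalue(
    statistic: str,
    dataset: GenotypeDataset,
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """One-sided permutation p-value for a differentiation statistic.

    ``statistic`` selects both the quantity and the randomisation unit:

    * ``"fst"`` — permute individuals among populations;
    * ``"fis"`` — permute gene copies among individuals within populations;
    * ``"fst_eq_rst"`` — permute allele sizes among allelic states within
      loci (tests whether stepwise-like mutation contributes, i.e.
      RST > FST under size permutation).

    ``p = (1 + #{perm >= observed}) / (n_perm + 1)``, never zero.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    if statistic == "fst":
        observed = fstats_wc(dataset)[1]

        def perm_stat():
            pops = dataset.pops.copy()
            rng.shuffle(pops)
            return fstats_wc(
                GenotypeDataset(alleles=dataset.alleles, pops=pops, pop_names=list(dataset.pop_names))
            )[1]

    elif statistic == "fis":
        observed = fstats_wc(dataset)[0]

        def perm_stat():
            return fstats_wc(_permute_fis(dataset, rng))[0]

    elif statistic == "fst_eq_rst":
        observed = rst_slatkin(dataset)

        def perm_stat():
            return rst_slatkin(_permute_sizes(dataset, rng))

    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    exceed = sum(perm_stat() >= observed for _ in range(n_perm))
    return (1.0 + exceed) / (n_perm + 1.0)


def pairwise_fst_matrix(dataset: GenotypeDataset, linearize: bool = False) -> pd.DataFrame:
    """Pairwise Weir-Cockerham FST between all population pairs.

    With ``linearize``, entries become ``FST/(1-FST)`` (infinite at
    FST = 1).  Diagonal is zero.
    """
    n = dataset.n_populations
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            fst = fstats_wc(dataset.subset_populations([i, j]))[1]
            if linearize:
                fst = np.inf if fst == 1.0 else fst / (1.0 - fst)
            mat[i, j] = mat[j, i] = fst
    return pd.DataFrame(mat, index=dataset.pop_names, columns=dataset.pop_names)


# --------------------------------------------------------------------------- #
# dataset-level summaries


def _pop_locus_counts(dataset: GenotypeDataset, pop_code: int) -> list[np.ndarray]:
    rows = dataset.population_indices(pop_code)
    out = []
    for locus in range(dataset.n_loci):
        geno = dataset.alleles[rows, locus, :]
        copies = geno[(geno != MISSING).all(axis=1)].ravel()
        out.append(np.unique(copies, return_counts=True)[1].astype(float))
    return out


def mean_expected_heterozygosity(dataset: GenotypeDataset, unbiased: bool = True) -> float:
    """He averaged over loci and populations (the model-selection statistic)."""
    vals = []
    for code in range(dataset.n_populations):
        per_locus, _ = expected_heterozygosity(_pop_locus_counts(dataset, code), unbiased=unbiased)
        vals.append(per_locus)
    return float(np.concatenate(vals).mean())


def summary_table(dataset: GenotypeDataset, g: int = 4, unbiased: bool = True):
    """Per-population diversity table plus overall differentiation.

    Returns ``(table, overall)``: a DataFrame with one row per population
    (columns n, A, Ar, Ho, He, f) followed by Mean and SD rows, and a dict
    with overall FIS/FST/FIT and RST.  Populations with fewer gene copies
    than the rarefaction base get NaN in the Ar column.
    """
    rows = []
    for code, name in enumerate(dataset.pop_names):
        counts = _pop_locus_counts(dataset, code)
        idx = dataset.population_indices(code)
        _, he = expected_heterozygosity(counts, unbiased=unbiased)
        try:
            _, ar = allelic_richness(counts, g=g)
        except ValueError:
            ar = float("nan")
        rows.append(
            {
                "Pop": name,
                "n": len(idx),
                "A": float(np.mean([len(c) for c in counts])),
                "Ar": ar,
                "Ho": observed_heterozygosity(dataset.alleles[idx]),
                "He": he,
                "f": population_inbreeding(dataset, code),
            }
        )
    table = pd.DataFrame(rows).set_index("Pop")
    stats_cols = ["n", "A", "Ar", "Ho", "He", "f"]
    mean_row = table[stats_cols].mean()
    sd_row = table[stats_cols].std(ddof=1)
    table.loc["Mean"] = mean_row
    table.loc["SD"] = sd_row
    fis, fst, fit = fstats_wc(dataset)
    overall = {"FIS": fis, "FST": fst, "FIT": fit, "RST": rst_slatkin(dataset)}
    return table, overall
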