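"""Independent brute-force oracles used only by the test suite.

These deliberately take a different computational route from the package:
the F-statistic oracle is a literal nested analysis of variance on 0/1
gene-copy indicators (sums of squares and mean squares), and the RST
oracle enumerates every pair of gene copies directly.
"""

import numpy as np

from refugia.genotypes import MISSING


def wc_fstats_bruteforce(dataset):
    """(FIS, FST, FIT) via indicator-variable nested ANOVA.

    For each allele at each locus, treats presence of the allele in a gene
    copy as a 0/1 response with gene copies nested in individuals nested in
    populations, forms the three mean squares, and converts them to
    variance components with the usual expected-mean-square coefficients.
    """
    a_sum = b_sum = c_sum = 0.0
    for locus in range(dataset.n_loci):
        geno = dataset.alleles[:, locus, :]
        ok = (geno != MISSING).all(axis=1)
        g = geno[ok]
        pops = dataset.pops[ok]
        codes = np.unique(pops)
        r = len(codes)
        if r < 2:
            continue
        n_i = np.array([(pops == c).sum() for c in codes], dtype=float)
        n_sum = n_i.sum()
        n_c = (n_sum - (n_i**2).sum() / n_sum) / (r - 1.0)
        for allele in np.unique(g):
            y = (g == allele).astype(float)  # (n_ind, 2)
            ybar = y.mean(axis=1)
            p_i = np.array([y[pops == c].mean() for c in codes])
            p_bar = (n_i * p_i).sum() / n_sum
            ssw = ((y - ybar[:, None]) ** 2).sum()
            ssi = 2.0 * sum(
                ((ybar[pops == c] - p_i[k]) ** 2).sum() for k, c in enumerate(codes)
            )
            ssp = 2.0 * (n_i * (p_i - p_bar) ** 2).sum()
            msw = ssw / n_sum
            msi = ssi / (n_sum - r)
            msp = ssp / (r - 1.0)
            c_sum += msw
            b_sum += (msi - msw) / 2.0
            a_sum += (msp - msi) / (2.0 * n_c)
    tot = a_sum + b_sum + c_sum
    fis = b_sum / (b_sum + c_sum) if (b_sum + c_sum) != 0 else float("nan")
    return fis, a_sum / tot, (a_sum + b_sum) / tot


def rst_bruteforce(dataset):
    """RST by direct enumeration of all pairs of gene copies."""

    def mean_pair_sq(x):
        x = np.asarray(x, dtype=float)
        total = 0.0
        count = 0
        for i in range(len(x)):
            for j in range(i + 1, len(x)):
                total += (x[i] - x[j]) ** 2
                count += 1
        return total / count

    num = den = 0.0
    for locus in range(dataset.n_loci):
        geno = dataset.alleles[:, locus, :]
        ok = (geno != MISSING).all(axis=1)
        sizes = geno[ok].astype(float)
        pops = dataset.pops[ok]
        pooled = sizes.ravel()
        if pooled.size < 2 or np.ptp(pooled) == 0:
            continue
        s_bar = mean_pair_sq(pooled)
        within = [
            mean_pair_sq(sizes[pops == c].ravel())
            for c in np.unique(pops)
            if (pops == c).sum() >= 1 and sizes[pops == c].size >= 2
        ]
        s_w = float(np.mean(within))
        num += s_bar - s_w
        den += s_bar
    return num / den


def mantel_exhaustive(mat_a, mat_b):
    """Observed r plus the exhaustive two-sided permutation p (tiny n)."""
    from itertools import permutations

    a = np.asarray(mat_a, dtype=float)
    b = np.asarray(mat_b, dtype=float)
    iu = np.triu_indices_from(a, k=1)
    va = a[iu]
    r_obs = np.corrcoef(va, b[iu])[0, 1]
    n = a.shape[0]
    rs = []
    for perm in permutations(range(n)):
        pb = b[np.ix_(perm, perm)]
        rs.append(np.corrcoef(va, pb[iu])[0, 1])
    rs = np.array(rs)
    p = (np.abs(rs) >= abs(r_obs) - 1e-12).mean()
    return r_obs, p
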