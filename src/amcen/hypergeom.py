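"""Cumulative hypergeometric test for shared-miRNA enrichment.

This is the statistical core of ceRNA pair calling: given a universe of N
miRNAs, an mRNA with n miRNA partners and an lncRNA with m partners, the
number of shared partners X under random overlap is hypergeometric, and a
pair is a ceRNA candidate when the observed shared count x is improbably
large.

Two tail conventions are provided because the published form of this test
is sometimes typeset with the sum running to x (giving P(X > x)) where the
standard enrichment tail is P(X >= x):

``tail="ge"``
    P(X >= x) = 1 - sum_{k=0}^{x-1} C(m,k) C(N-m, n-k) / C(N,n).
    The conservative standard; the default everywhere in this package.
``tail="gt"``
    P(X > x) = 1 - sum_{k=0}^{x} C(m,k) C(N-m, n-k) / C(N,n).

Both are evaluated through the hypergeometric survival function (log-space
internally in scipy), never by naive binomial sums, and clamped to [0, 1].
"""

from __future__ import annotations

from scipy.stats import hypergeom

VALID_TAILS = ("ge", "gt")


def hypergeom_cerna_p(N: int, n: int, m: int, x: int, tail: str = "ge") -> float:
    """Upper-tail probability of sharing x of N universe miRNAs.

    Parameters
    ----------
    N : total number of distinct miRNAs in the run's universe (from the
        aberrant-gene-to-miRNA interaction sub-table).
    n : number of miRNA partners of the mRNA.
    m : number of miRNA partners of the lncRNA, restricted to the universe.
    x : number of shared partners.
    tail : "ge" for P(X >= x) (default), "gt" for P(X > x).
    """
    if N < 1:
        raise ValueError(f"universe size N must be >= 1, got N={N}")
    if not 0 <= n <= N:
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    if not 0 <= m <= N:
        raise ValueError(f"need 0 <= m <= N, got m={m}, N={N}")
    if not 0 <= x <= min(n, m):
        raise ValueError(f"need 0 <= x <= min(n, m), got x={x}, min(n, m)={min(n, m)}")
    if tail not in VALID_TAILS:
        raise ValueError(f"tail must be one of {VALID_TAILS}, got {tail!r}")
    # X ~ Hypergeom(M=N, n=m, N=n) in scipy's parameterization; sf(k) = P(X > k)
    k = x if tail == "gt" else x - 1
    p = hypergeom.sf(k, N, m, n)
    return float(min(1.0, max(0.0, p)))
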