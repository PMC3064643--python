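"""Frequency-spectrum summary statistics and neutrality tests.

Implements the estimators and tests used throughout the package: mean
pairwise differences (theta_pi), Watterson's theta_S, Tajima's D, Fu & Li's
D* (the no-outgroup version, with the corrected variance constants), the
theoretical minimum Dmin of Tajima's D at the all-singleton extreme, the
scaled ratio D/|Dmin|, and empirical neutral confidence bounds obtained
from standard coalescent simulations conditioned on the number of
segregating sites.

Sign conventions
----------------
``d_ratio`` divides D by the *absolute value* of Dmin so the ratio keeps
the sign of D and equals -1 exactly when every segregating site is a
singleton.  This is the only convention under which the ratio is negative
for negative D and bounded below by -1.

Statistics are undefined when S = 0; such calls raise
:class:`UndefinedStatisticError` rather than returning 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genealogy import Genealogy
from .overlay import HaplotypeMatrix

__all__ = [
    "UndefinedStatisticError",
    "NeutralitySummary",
    "theta_pi",
    "theta_W",
    "tajimas_D",
    "fu_li_Dstar",
    "d_min",
    "d_ratio",
    "neutral_bounds",
    "kingman_tree",
    "summarize_matrix",
]


class UndefinedStatisticError(ValueError):
    """The statistic is undefined for this input (e.g. S = 0)."""


# --------------------------------------------------------------------- inputs


def _as_counts(M, folded: bool = False) -> tuple[int, np.ndarray]:
    """Normalize input to (n, derived counts per segregating site)."""
    if isinstance(M, HaplotypeMatrix):
        n = M.n
        counts = M.derived_counts()
    else:
        n, counts = M
        counts = np.asarray(counts, dtype=np.int64)
    if n < 2:
        raise UndefinedStatisticError("need at least 2 samples")
    if np.any(counts < 0) or np.any(counts > n):
        raise ValueError("derived counts must be in [0, n]")
    counts = counts[(counts > 0) & (counts < n)]  # drop monomorphic columns
    if folded:
        counts = np.minimum(counts, n - counts)
    return n, counts


# ------------------------------------------------------------------ constants


def harmonic(n: int, power: int = 1) -> float:
    return float(sum(1.0 / i**power for i in range(1, n)))


def tajima_constants(n: int) -> dict[str, float]:
    a1 = harmonic(n)
    a2 = harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "e1": e1, "e2": e2}


def fu_li_dstar_constants(n: int) -> dict[str, float]:
    """u* and v* of Fu & Li's D*, including the published correction."""
    a1 = harmonic(n)
    a2 = harmonic(n, 2)
    an1 = a1 + 1.0 / n  # a_{n+1}
    cn = 2.0 * (n * a1 - 2 * (n - 1)) / ((n - 1) * (n - 2))
    dn = (
        cn
        + (n - 2) / (n - 1) ** 2
        + (2.0 / (n - 1)) * (1.5 - (2 * an1 - 3) / (n - 2) - 1.0 / n)
    )
    nr = n / (n - 1.0)
    vstar = (nr**2 * a2 + a1**2 * dn - 2 * n * a1 * (a1 + 1) / (n - 1) ** 2) / (
        a1**2 + a2
    )
    ustar = nr * (a1 - nr) - vstar
    return {"a1": a1, "ustar": ustar, "vstar": vstar}


# ----------------------------------------------------------------- estimators


def theta_pi(M, folded: bool = False) -> float:
    """Mean pairwise differences over all n(n-1)/2 unordered pairs."""
    n, counts = _as_counts(M, folded)
    if counts.size == 0:
        return 0.0
    # a column with derived count c contributes 2 c (n-c) / (n (n-1))
    return float(np.sum(2.0 * counts * (n - counts)) / (n * (n - 1)))


def theta_W(S: int, n: int) -> float:
    """Watterson's estimator S / a1."""
    if n < 2:
        raise UndefinedStatisticError("need at least 2 samples")
    if S == 0:
        return 0.0
    return S / harmonic(n)


def tajimas_D(M, folded: bool = False) -> float:
    n, counts = _as_counts(M, folded)
    S = counts.size
    if S == 0:
        raise UndefinedStatisticError("Tajima's D undefined for S = 0")
    if n < 4:
        # for n = 3 the variance constants vanish identically (pi == S/a1)
        raise UndefinedStatisticError("Tajima's D needs at least 4 samples")
    c = tajima_constants(n)
    pi = theta_pi((n, counts))
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return (pi - S / c["a1"]) / math.sqrt(var)


def fu_li_Dstar(M, folded: bool = False) -> float:
    """Fu & Li's D* (no outgroup), eta = S under infinite sites."""
    n, counts = _as_counts(M, folded)
    S = counts.size
    if S == 0:
        raise UndefinedStatisticError("Fu & Li's D* undefined for S = 0")
    if n < 3:
        raise UndefinedStatisticError("D* needs at least 3 samples")
    k = fu_li_dstar_constants(n)
    eta = S
    eta_s = int(np.sum(counts == 1))  # folded inputs already hold minor counts
    num = (n / (n - 1.0)) * eta - k["a1"] * eta_s
    var = k["ustar"] * eta + k["vstar"] * eta * eta
    return num / math.sqrt(var)


def d_min(n: int, S: int) -> float:
    """Tajima's D at the all-singleton extreme (pi replaced by 2S/n)."""
    if n < 4:
        # same degeneracy as D itself: the variance constants vanish at n=3
        raise UndefinedStatisticError("Dmin needs at least 4 samples")
    if S < 1:
        raise UndefinedStatisticError("Dmin undefined for S = 0")
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return (2.0 * S / n - S / c["a1"]) / math.sqrt(var)


def d_ratio(D: float, Dmin: float) -> float:
    """D scaled by |Dmin|; -1 at the singleton extreme, sign follows D."""
    if Dmin == 0:
        raise UndefinedStatisticError("Dmin is zero; ratio undefined")
    return D / abs(Dmin)


# ------------------------------------------------------ neutral null process


def kingman_tree(
    n: int, pop_size: float, rng: np.random.Generator, group: str = "pop"
) -> Genealogy:
    """Standard single-population coalescent genealogy for n samples.

    Waiting times are exponential with rate C(k,2)/pop_size generations,
    the continuous-time limit of a haploid Wright-Fisher population of
    ``pop_size`` individuals.  Branches are marked fully asexual so the
    tree can stand in for a one-clone population in either overlay mode.
    """
    g = Genealogy()
    lineages = []
    for i in range(n):
        nid = g.add_node(f"t{i}", 0.0, False, group)
        lineages.append(nid)
    g.samples = list(lineages)
    t = 0.0
    k = n
    nxt = 0
    while k > 1:
        rate = k * (k - 1) / 2.0 / pop_size
        t += rng.exponential(1.0 / rate)
        i, j = rng.choice(k, size=2, replace=False)
        a, b = lineages[i], lineages[j]
        anc = g.add_node(f"a{nxt}", t, False, group)
        nxt += 1
        g.add_branch(anc, a, t - g.nodes[a].time)
        g.add_branch(anc, b, t - g.nodes[b].time)
        lineages = [x for m, x in enumerate(lineages) if m not in (i, j)]
        lineages.append(anc)
        k -= 1
    g.root = lineages[0]
    g.nodes[g.root].is_sexual = True
    return g


def _sfs_counts_kingman(n: int, S: int, rng: np.random.Generator) -> np.ndarray:
    """Derived counts of S sites overlaid on one Kingman tree (fast path)."""
    # simulate the tree implicitly: track subtended-tip counts per lineage
    sizes = [1] * n
    lengths: list[float] = []
    subtend: list[int] = []
    k = n
    while k > 1:
        rate = k * (k - 1) / 2.0
        dt = rng.exponential(1.0 / rate)
        for sz in sizes:
            lengths.append(dt)
            subtend.append(sz)
        i, j = rng.choice(k, size=2, replace=False)
        merged = sizes[i] + sizes[j]
        sizes = [sz for m, sz in enumerate(sizes) if m not in (i, j)]
        sizes.append(merged)
        k -= 1
    # accumulate total length per subtended size, excluding size-n branches
    arr_len = np.zeros(n, dtype=float)
    for sz, ln in zip(subtend, lengths):
        if sz < n:
            arr_len[sz] += ln
    w = arr_len[1:n]
    counts = rng.multinomial(S, w / w.sum())
    return np.repeat(np.arange(1, n), counts)


def neutral_bounds(
    n: int,
    S: int,
    stat: str = "D",
    reps: int = 1000,
    rng: np.random.Generator | None = None,
    observed: float | None = None,
) -> dict[str, float]:
    """Empirical 95% neutral interval for D or D* conditioned on (n, S).

    Simulates ``reps`` standard coalescent genealogies, overlays exactly S
    sites on each and computes the statistic.  ``lo``/``hi`` are the
    2.5%/97.5% quantiles; if ``observed`` is given, ``p_value`` is its
    two-tailed empirical position.
    """
    if reps < 100:
        raise ValueError("need at least 100 replicates for stable bounds")
    if rng is None:
        rng = np.random.default_rng()
    fn = tajimas_D if stat == "D" else fu_li_Dstar
    if stat not in ("D", "Dstar"):
        raise ValueError("stat must be 'D' or 'Dstar'")
    vals = np.empty(reps)
    for r in range(reps):
        counts = _sfs_counts_kingman(n, S, rng)
        vals[r] = fn((n, counts))
    lo, hi = np.quantile(vals, [0.025, 0.975])
    out = {"lo": float(lo), "hi": float(hi), "mean": float(vals.mean())}
    if observed is not None:
        lower = float(np.mean(vals <= observed))
        upper = float(np.mean(vals >= observed))
        out["p_value"] = min(1.0, 2.0 * min(lower, upper))
    return out


# -------------------------------------------------------------------- summary


@dataclass
class NeutralitySummary:
    n: int
    S: int
    eta_s: int
    theta_pi: float
    theta_S: float
    D: float | None
    Dstar: float | None
    Dmin: float | None
    D_ratio: float | None
    p_lower: float | None = None
    p_upper: float | None = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def summarize_matrix(
    M: HaplotypeMatrix,
    folded: bool = False,
    bounds_reps: int = 0,
    rng: np.random.Generator | None = None,
) -> NeutralitySummary:
    """Full summary of one dataset; optionally with neutral tail positions."""
    n = M.n
    counts = M.derived_counts()
    if folded:
        counts = np.minimum(counts, n - counts)
    S = int(counts.size)
    eta_s = int(np.sum(counts == 1))
    pi = theta_pi((n, counts)) if S else 0.0
    tw = theta_W(S, n)
    if S == 0:
        return NeutralitySummary(n, 0, 0, 0.0, 0.0, None, None, None, None)
    # undefined statistics propagate as None (blank row cells), not zeros
    D = tajimas_D((n, counts)) if n >= 4 else None
    Ds = fu_li_Dstar((n, counts)) if n >= 3 else None
    Dm = d_min(n, S) if n >= 4 else None
    Dr = d_ratio(D, Dm) if (D is not None and Dm) else None
    p_lo = p_hi = None
    if bounds_reps and D is not None:
        if rng is None:
            rng = np.random.default_rng()
        b = neutral_bounds(n, S, "D", bounds_reps, rng, observed=D)
        p_lo = float(D < b["lo"])
        p_hi = float(D > b["hi"])
    return NeutralitySummary(n, S, eta_s, pi, tw, D, Ds, Dm, Dr, p_lo, p_hi)
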