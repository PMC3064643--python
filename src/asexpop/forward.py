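"""Individual-based forward simulator of an asexual complex.

A haploid clonal population of ``N`` individuals is split into ``d`` demes
of ``N/d`` arranged on a finite linear stepping-stone (demes exchange
migrants only with their immediate neighbours; the terminal demes have a
single neighbour).  Each generation, in order:

1. reproduction: within each deme, every offspring picks a parent with
   probability proportional to its fitness ``(1 - s)^k``, where ``k`` is
   the parent's count of deleterious mutations (Wright-Fisher sampling
   with selection);
2. migration: for each adjacent deme pair, a binomial number of
   individuals is exchanged symmetrically so deme sizes stay constant;
3. clone recruitment: ``Poisson(c)`` new clone founders replace uniformly
   chosen residents of the first deme.  A founder carries a fresh clone
   identity and, by default, zero deleterious mutations (sexual
   reproduction is assumed to purge the load); its pedigree parent is the
   single sexual ancestor shared by all founders;
4. mutation: every individual gains ``Poisson(U)`` new deleterious
   mutations.

The event order (a founder is censused before it mutates) is a documented
constant of the model.  At the end of the run, ``z`` individuals per deme
are sampled and their pedigree is traced back; all founder lineages attach
to one star-shaped sexual root, and each branch records how many of its
generations were spent inside a clone (all of them, except the stem
between a founder and the sexual root).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genealogy import Genealogy, merge_all
from .overlay import overlay_fixed_S_counts, OverlayError
from .neutrality import tajimas_D, fu_li_Dstar, neutral_bounds

__all__ = ["IBSParams", "ForwardResult", "run_forward", "power_profile"]


@dataclass
class IBSParams:
    N: int = 500                 # total population size
    d: int = 1                   # number of asexual demes
    m: float = 0.0               # per-generation migration probability
    c: float = 1e-3              # clone recruitment rate into deme 1
    U: float = 0.5               # deleterious mutation rate (Poisson mean)
    s: float = 0.0               # selection coefficient per mutation
    z: int = 5                   # samples drawn per deme
    generations: int | None = None  # run length; default 10 N (burn-in rule)
    founder_load: str = "none"   # 'none' | 'equilibrium'
    seed: int | None = None

    def validate(self) -> None:
        if self.N < 1 or self.d < 1 or self.N % self.d:
            raise ValueError("N must be positive and divisible by d")
        if not (0 <= self.m <= 1) or self.c < 0 or self.U < 0:
            raise ValueError("m, c must be probabilities/rates >= 0")
        if not (0 <= self.s < 1):
            raise ValueError("s must be in [0, 1)")
        if self.z > self.N // self.d:
            raise ValueError("z exceeds the deme size")
        if self.founder_load not in ("none", "equilibrium"):
            raise ValueError("founder_load must be 'none' or 'equilibrium'")

    @property
    def run_length(self) -> int:
        return self.generations if self.generations is not None else 10 * self.N


@dataclass
class ForwardResult:
    genealogy: Genealogy
    mean_fitness: np.ndarray        # per generation
    final_k_distribution: np.ndarray  # counts of individuals per k
    clone_census: np.ndarray        # number of distinct extant clones per gen
    mean_k: np.ndarray              # per generation
    n_founder_attachments: int = 0


def _sample_founder_k(p: IBSParams, rng: np.random.Generator, size: int) -> np.ndarray:
    if p.founder_load == "none" or p.s == 0:
        return np.zeros(size, dtype=np.int64)
    # deterministic mutation-selection balance of a sexual population:
    # k ~ Poisson(U/s)
    return rng.poisson(p.U / p.s, size=size)


def run_forward(
    params: IBSParams, rng: np.random.Generator | None = None
) -> ForwardResult:
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    N, d = params.N, params.d
    size = N // d
    T = params.run_length
    if T < 1:
        raise ValueError("run length must be >= 1")

    k = _sample_founder_k(params, rng, N)
    clone = np.arange(N, dtype=np.int64)  # every initial individual founds a clone
    next_clone = N
    # founder_gen[i] < 0 marks "individual i of this generation is a founder"
    parents = np.empty((T, N), dtype=np.int32)
    is_founder = np.zeros((T + 1, N), dtype=bool)
    is_founder[0, :] = True

    mean_fitness = np.empty(T + 1)
    mean_k = np.empty(T + 1)
    clone_census = np.empty(T + 1, dtype=np.int64)
    log1ms = np.log1p(-params.s) if params.s > 0 else 0.0

    def census(t: int) -> None:
        mean_fitness[t] = float(np.mean(np.exp(k * log1ms))) if params.s > 0 else 1.0
        mean_k[t] = float(k.mean())
        clone_census[t] = len(np.unique(clone))

    census(0)
    deme_slices = [slice(i * size, (i + 1) * size) for i in range(d)]

    for t in range(T):
        # 1) reproduction with selection, per deme
        newp = np.empty(N, dtype=np.int32)
        for i, sl in enumerate(deme_slices):
            if params.s > 0:
                w = np.exp(k[sl] * log1ms)
                cum = np.cumsum(w)
                pick = np.searchsorted(cum, rng.random(size) * cum[-1])
                pick = np.minimum(pick, size - 1)
            else:
                pick = rng.integers(0, size, size)
            newp[sl] = pick.astype(np.int32) + sl.start
        parents[t] = newp
        k = k[newp]
        clone = clone[newp]

        # 2) stepping-stone migration: symmetric exchange keeps sizes fixed
        if params.m > 0 and d > 1:
            for i in range(d - 1):
                n_sw = rng.binomial(size, params.m)
                if n_sw == 0:
                    continue
                a = rng.choice(size, n_sw, replace=False) + i * size
                b = rng.choice(size, n_sw, replace=False) + (i + 1) * size
                k[a], k[b] = k[b].copy(), k[a].copy()
                clone[a], clone[b] = clone[b].copy(), clone[a].copy()
                pa, pb = parents[t][a].copy(), parents[t][b].copy()
                parents[t][a], parents[t][b] = pb, pa

        # 3) clone recruitment into the first deme
        n_new = rng.poisson(params.c)
        if n_new:
            targets = rng.choice(size, min(n_new, size), replace=False)
            for tgt in targets:
                k[tgt] = _sample_founder_k(params, rng, 1)[0]
                clone[tgt] = next_clone
                next_clone += 1
                is_founder[t + 1, tgt] = True

        # 4) mutation
        if params.U > 0:
            k = k + rng.poisson(params.U, N)

        census(t + 1)

    # ------------------------------------------------------------- pedigree
    g = Genealogy()
    tip_idx = []
    for i in range(d):
        tip_idx.extend(
            (rng.choice(size, params.z, replace=False) + i * size).tolist()
        )
    # active lineages: individual index (within current generation) -> node
    lineages: dict[int, tuple[str, float]] = {}
    for j, idx in enumerate(tip_idx):
        deme = idx // size
        nid = g.add_node(f"d{deme}_{j}", 0.0, False, f"deme{deme}")
        g.samples.append(nid)
        lineages[idx] = (nid, 0.0)
    nxt = 0

    root_children: list[tuple[str, float, float]] = []  # (node, time, asex_gens)
    n_attach = 0
    for t_back, t_fwd in enumerate(range(T, 0, -1), start=1):
        # lineages sitting on founders attach to the sexual root; the
        # remainder of their branch up to the root is the sexual stem
        for idx in list(lineages):
            if is_founder[t_fwd, idx]:
                node, t0 = lineages.pop(idx)
                root_children.append((node, t0, (t_back - 1) - t0))
                n_attach += 1
        if not lineages:
            break
        # step all remaining lineages one generation back, merging siblings
        moved: dict[int, list[tuple[str, float]]] = {}
        for idx, (node, t0) in lineages.items():
            moved.setdefault(int(parents[t_fwd - 1][idx]), []).append((node, t0))
        lineages = {}
        for pidx, members in moved.items():
            if len(members) == 1:
                lineages[pidx] = members[0]
            else:
                anc = merge_all(
                    g,
                    [mm[0] for mm in members],
                    float(t_back),
                    f"m{nxt}",
                    False,
                    None,
                    [t_back - mm[1] for mm in members],
                )
                nxt += 1
                lineages[pidx] = (anc, float(t_back))
    # anything still alive at generation 0 sits on an initial founder
    for idx, (node, t0) in lineages.items():
        root_children.append((node, t0, T - t0))
        n_attach += 1

    g.root = merge_all(
        g,
        [ch[0] for ch in root_children],
        float(T),
        "root",
        True,
        "sexual",
        [ch[2] for ch in root_children],
    )
    g.validate()

    return ForwardResult(
        genealogy=g,
        mean_fitness=mean_fitness,
        final_k_distribution=np.bincount(k),
        clone_census=clone_census,
        mean_k=mean_k,
        n_founder_attachments=n_attach,
    )


def power_profile(
    params: IBSParams,
    reps: int,
    S: int,
    stat: str = "D",
    mode: str = "pruned",
    rng: np.random.Generator | None = None,
    bounds_reps: int = 1000,
) -> dict[str, float]:
    """Monte-Carlo power of a neutrality statistic against the simulated model.

    Runs ``reps`` forward simulations, overlays ``S`` sites on each sampled
    genealogy (``mode`` selects total or asexual-only branch weighting),
    computes the statistic, and reports the mean together with the
    fractions of replicates falling below/above the 95% neutral interval
    for the realized sample size.
    """
    if reps < 1 or S < 1:
        raise ValueError("reps and S must be >= 1")
    if stat not in ("D", "Dstar"):
        raise ValueError("stat must be 'D' or 'Dstar'")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = params.z * params.d
    bounds = neutral_bounds(n, S, stat, bounds_reps, rng)
    fn = tajimas_D if stat == "D" else fu_li_Dstar
    vals = []
    excluded = 0
    for _ in range(reps):
        res = run_forward(params, rng)
        try:
            counts = overlay_fixed_S_counts(res.genealogy, S, mode, rng)
            counts = counts[(counts >= 1) & (counts <= n - 1)]
            if counts.size == 0:
                excluded += 1
                continue
            vals.append(fn((n, counts)))
        except OverlayError:
            excluded += 1
    vals = np.asarray(vals)
    return {
        "mean": float(vals.mean()),
        "frac_below_CI": float(np.mean(vals < bounds["lo"])),
        "frac_above_CI": float(np.mean(vals > bounds["hi"])),
        "lo": bounds["lo"],
        "hi": bounds["hi"],
        "n_excluded": excluded,
        "n_used": int(vals.size),
    }
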