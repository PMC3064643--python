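"""Backward-time coalescent simulator of a sexual-asexual complex.

The complex consists of ``d_C`` sexual demes (finite island model,
per-generation backward migration probability ``m_C``) and ``L_C`` clones
whose sizes partition a total asexual population of ``N_C`` individuals
according to a broken-stick model.  Looking backward in time, each clone is
founded by a single sexual ancestor: either with a constant per-generation
probability P' (neutral clonal turnover) or with a hazard that rises with
candidate clone age a' as 1 - (1 - f')^a' (age-dependent clonal decay).
Within an unfounded clone, lineage pairs coalesce with probability
1/(clone size) per generation; at founding, every remaining lineage of the
clone merges into one founder node which is placed in a uniformly chosen
sexual deme and behaves as a sexual lineage from then on.  Sexual lineages
migrate among demes and coalesce pairwise within a deme with probability
1/(deme size) per generation, until the grand (sexual) MRCA.

Branch ``asexual_gens`` accrue only while a lineage sits inside an
unfounded clone, which is exactly the portion of the genealogy the
"pruned" overlay weights.

The process is a discrete-generation model.  It is simulated event-to-event
with geometric waiting times (memoryless in the homogeneous stretches
between events); when per-generation event probabilities are not small the
simulator falls back to generation-by-generation stepping, so small demes
are handled exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genealogy import Genealogy, GenealogyError, merge_all

__all__ = [
    "CoalParams",
    "broken_stick_sizes",
    "founding_hazard",
    "sample_founding_time",
    "run_coalescent",
    "asexual_time_experiment",
]

# above this per-generation event probability, step generation by generation
_EXACT_STEP_P = 0.2


@dataclass
class CoalParams:
    """Parameters of the backward coalescent of one complex."""

    L_C: int = 10                # number of clones
    N_C: int = 25_000            # total asexual population size
    z_C: int = 5                 # samples per clone
    d_C: int = 2                 # sexual demes
    N_sex: int = 25_000          # total sexual population size
    z_sex: int = 0               # samples per sexual deme
    m_C: float = 1e-3            # backward migration prob between sexual demes
    hazard_mode: str = "neutral"  # 'neutral' | 'decay' | 'off'
    P_prime: float = 1e-3        # constant founding probability (neutral)
    f_prime: float = 0.0         # per-generation fitness-loss rate (decay)
    seed: int | None = None

    def validate(self) -> None:
        if self.L_C < 1 or self.N_C < self.L_C:
            raise ValueError("need L_C >= 1 clones and N_C >= L_C individuals")
        if self.z_C < 1:
            raise ValueError("z_C must be >= 1")
        if self.hazard_mode not in ("neutral", "decay", "off"):
            raise ValueError(f"unknown hazard_mode {self.hazard_mode!r}")
        if self.hazard_mode == "neutral" and not (0 < self.P_prime <= 1):
            raise ValueError("neutral mode needs 0 < P_prime <= 1")
        if self.hazard_mode == "decay" and not (0 < self.f_prime < 1):
            raise ValueError("decay mode needs 0 < f_prime < 1")
        if self.hazard_mode != "off":
            if self.d_C < 1 or self.N_sex < self.d_C:
                raise ValueError("need d_C >= 1 sexual demes with N_sex >= d_C")
        if not (0 <= self.m_C <= 1):
            raise ValueError("m_C must be a probability")
        if self.z_sex and self.hazard_mode == "off":
            raise ValueError("sexual samples require a founding hazard")


def broken_stick_sizes(
    N_C: int, L_C: int, rng: np.random.Generator
) -> np.ndarray:
    """Partition N_C individuals over L_C clones via uniform breakpoints.

    L_C - 1 uniform breakpoints on (0, N_C) cut the stick; the pieces are
    rounded to positive integers summing exactly to N_C by largest
    remainders, with a minimum size of 1.
    """
    if L_C < 1:
        raise ValueError("L_C must be >= 1")
    if N_C < L_C:
        raise ValueError(f"cannot split {N_C} individuals into {L_C} clones")
    if L_C == 1:
        return np.array([N_C], dtype=np.int64)
    cuts = np.sort(rng.uniform(0.0, N_C, size=L_C - 1))
    raw = np.diff(np.concatenate([[0.0], cuts, [N_C]]))
    base = np.floor(raw).astype(np.int64)
    rem = N_C - base.sum()
    order = np.argsort(-(raw - base))  # largest fractional remainders first
    base[order[: int(rem)]] += 1
    # enforce positivity: steal from the largest piece
    while np.any(base < 1):
        base[np.argmax(base)] -= 1
        base[np.argmin(base)] += 1
    assert base.sum() == N_C
    return base


def founding_hazard(
    mode: str, P_prime: float, f_prime: float, a_prime: int
) -> float:
    """Per-generation probability that a clone of candidate age a' is founded."""
    if a_prime < 1:
        raise ValueError("a_prime counts backward generations, >= 1")
    if mode == "neutral":
        if not (0 <= P_prime <= 1):
            raise ValueError("P_prime must be a probability")
        return P_prime
    if mode == "decay":
        if not (0 <= f_prime < 1):
            raise ValueError("f_prime must be in [0, 1)")
        return 1.0 - (1.0 - f_prime) ** a_prime
    raise ValueError(f"unknown hazard mode {mode!r}")


def sample_founding_time(
    mode: str, P_prime: float, f_prime: float, rng: np.random.Generator
) -> int:
    """Backward generation at which the clone's founding fires (>= 1).

    The hazard is evaluated generation by generation, so decay-mode times
    follow P(T > t) = (1 - f')^(t(t+1)/2) by construction.
    """
    if mode == "neutral":
        return int(rng.geometric(P_prime))
    if mode == "decay":
        t = 0
        while True:
            t += 1
            if rng.random() < founding_hazard("decay", 0.0, f_prime, t):
                return t
            if t > 10_000_000:  # pragma: no cover - pathological f'
                raise RuntimeError("founding did not fire; f_prime too small")
    raise ValueError(f"unknown hazard mode {mode!r}")


# ----------------------------------------------------------------- simulator


@dataclass
class _Lineage:
    node: str
    time: float          # time (backward gens) of the node
    asex_until: float    # lineage was asexual from `time` until this time
    deme: int            # sexual deme index once sexual


def _clone_phase(
    g: Genealogy,
    params: CoalParams,
    clone: int,
    size: int,
    T_found: int,
    rng: np.random.Generator,
) -> _Lineage:
    """Coalesce z_C tip lineages inside one clone until its founding."""
    group = f"clone{clone}"
    lineages = []
    for j in range(params.z_C):
        nid = g.add_node(f"c{clone}_{j}", 0.0, False, group)
        lineages.append(_Lineage(nid, 0.0, 0.0, -1))
        g.samples.append(nid)
    t = 0
    nxt = 0
    while len(lineages) > 1 and t < T_found:
        k = len(lineages)
        p = 1.0 - (1.0 - 1.0 / size) ** (k * (k - 1) / 2.0)
        if p >= _EXACT_STEP_P:
            dt = 1
            fire = rng.random() < p
        else:
            dt = int(rng.geometric(p)) if p > 0 else T_found - t + 1
            fire = True
        t += dt
        if t > T_found or not fire:
            t = min(t, T_found)
            continue
        i, j = rng.choice(k, size=2, replace=False)
        a, b = lineages[i], lineages[j]
        anc = g.add_node(f"cc{clone}_{nxt}", float(t), False, group)
        nxt += 1
        g.add_branch(anc, a.node, t - a.time)   # fully asexual branch
        g.add_branch(anc, b.node, t - b.time)
        lineages = [x for m, x in enumerate(lineages) if m not in (i, j)]
        lineages.append(_Lineage(anc, float(t), float(t), -1))
    # founding: merge whatever remains into a single sexual founder
    if params.hazard_mode == "off":
        # no founding: the last lineage is the clone's internal MRCA
        if len(lineages) != 1:
            raise GenealogyError("clone phase ended with multiple lineages")
        return lineages[0]
    if len(lineages) > 1:
        founder = merge_all(
            g,
            [ln.node for ln in lineages],
            float(T_found),
            f"f{clone}",
            True,
            group,
            [T_found - ln.time for ln in lineages],
        )
        out = _Lineage(founder, float(T_found), float(T_found), -1)
    else:
        # single lineage: phase flips at T_found without a node
        ln = lineages[0]
        out = _Lineage(ln.node, ln.time, float(T_found), -1)
    out.deme = int(rng.integers(params.d_C))
    return out


def run_coalescent(
    params: CoalParams, rng: np.random.Generator | None = None
) -> Genealogy:
    """Simulate one genealogy of the complex back to the grand sexual MRCA."""
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)

    if params.z_C > params.N_C // params.L_C:
        raise ValueError(
            f"z_C={params.z_C} cannot be drawn from every clone: no partition "
            f"of {params.N_C} into {params.L_C} clones supports it"
        )
    # condition the broken stick on every clone holding at least z_C
    # individuals (the sample must be drawable from each clone)
    for _ in range(1000):
        sizes = broken_stick_sizes(params.N_C, params.L_C, rng)
        if sizes.min() >= params.z_C:
            break
    else:  # pragma: no cover - astronomically unlikely given the guard
        raise RuntimeError("could not draw clone sizes supporting z_C")

    g = Genealogy()
    g.samples = []

    if params.hazard_mode == "off":
        if params.L_C != 1:
            raise ValueError("hazard_mode='off' requires a single clone")
        lin = _clone_phase(g, params, 0, int(sizes[0]), np.iinfo(np.int64).max, rng)
        g.root = lin.node
        g.nodes[g.root].is_sexual = True
        g.validate()
        return g

    founding_times = [
        sample_founding_time(params.hazard_mode, params.P_prime, params.f_prime, rng)
        for _ in range(params.L_C)
    ]
    active: list[tuple[float, _Lineage]] = []  # (activation time, lineage)
    for i in range(params.L_C):
        lin = _clone_phase(g, params, i, int(sizes[i]), founding_times[i], rng)
        active.append((float(founding_times[i]), lin))

    deme_size = params.N_sex // params.d_C
    if params.z_sex:
        if params.z_sex > deme_size:
            raise ValueError("z_sex exceeds the sexual deme size")
        for j in range(params.d_C):
            for k in range(params.z_sex):
                nid = g.add_node(f"s{j}_{k}", 0.0, True, f"deme{j}")
                g.samples.append(nid)
                active.append((0.0, _Lineage(nid, 0.0, 0.0, j)))

    # ---------------- sexual phase: event-driven island-model coalescent
    pending = sorted(active, key=lambda x: x[0])
    t = 0.0
    sexual: list[_Lineage] = []
    cap = 1e3 * params.N_sex + max(founding_times)
    nxt = 0
    while pending or len(sexual) > 1:
        # activate lineages whose founding time has been reached
        while pending and pending[0][0] <= t + 1e-9:
            sexual.append(pending.pop(0)[1])
        L = len(sexual)
        if L <= 1 and pending:
            t = pending[0][0]
            continue
        if L <= 1 and not pending:
            break
        per_deme = np.bincount(
            [ln.deme for ln in sexual], minlength=params.d_C
        )
        p_mig = 1.0 - (1.0 - params.m_C) ** L if params.d_C > 1 else 0.0
        p_coal = 1.0 - float(
            np.prod(
                [(1 - 1.0 / deme_size) ** (kj * (kj - 1) / 2.0) for kj in per_deme]
            )
        )
        p_any = 1.0 - (1.0 - p_mig) * (1.0 - p_coal)
        if p_any <= 0:
            if pending:
                t = pending[0][0]
                continue
            raise GenealogyError("isolated lineages can never coalesce")
        if p_any >= _EXACT_STEP_P:
            dt = 1.0
        else:
            dt = float(rng.geometric(p_any))
        t_next_activation = pending[0][0] if pending else np.inf
        if t + dt > t_next_activation:
            t = t_next_activation
            continue
        t += dt
        if t > cap:
            raise RuntimeError(
                f"coalescent did not terminate within {cap:.0f} generations"
            )
        if p_any >= _EXACT_STEP_P and rng.random() >= p_any:
            continue
        # choose event type proportionally to hazards
        if rng.random() < p_mig / (p_mig + p_coal):
            ln = sexual[int(rng.integers(L))]
            if params.d_C == 2:
                ln.deme = 1 - ln.deme
            else:
                ln.deme = int(
                    rng.choice([d for d in range(params.d_C) if d != ln.deme])
                )
        else:
            weights = per_deme * (per_deme - 1) / 2.0
            deme = int(rng.choice(params.d_C, p=weights / weights.sum()))
            idxs = [i for i, ln in enumerate(sexual) if ln.deme == deme]
            i, j = rng.choice(len(idxs), size=2, replace=False)
            a, b = sexual[idxs[i]], sexual[idxs[j]]
            anc = g.add_node(f"sx{nxt}", t, True, f"deme{deme}")
            nxt += 1
            g.add_branch(anc, a.node, max(0.0, a.asex_until - a.time))
            g.add_branch(anc, b.node, max(0.0, b.asex_until - b.time))
            sexual = [
                ln for m, ln in enumerate(sexual) if m not in (idxs[i], idxs[j])
            ]
            sexual.append(_Lineage(anc, t, t, deme))

    g.root = sexual[0].node
    g.nodes[g.root].is_sexual = True
    g.validate()
    return g


def asexual_time_experiment(
    param_grid: list[CoalParams],
    reps: int,
    rng: np.random.Generator | None = None,
):
    """Distribution of the asexual time fraction per parameter combination.

    Returns a pandas DataFrame with one row per parameter set carrying the
    sampled fractions and their quartiles, the raw material of the
    box-plot comparison of decay strength and sexual fragmentation.
    """
    import pandas as pd

    if reps < 1:
        raise ValueError("reps must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    rows = []
    for idx, p in enumerate(param_grid):
        fracs = np.empty(reps)
        for r in range(reps):
            fracs[r] = run_coalescent(p, rng).asexual_fraction()
        q25, q50, q75 = np.quantile(fracs, [0.25, 0.5, 0.75])
        rows.append(
            {
                "params_index": idx,
                "hazard_mode": p.hazard_mode,
                "P_prime": p.P_prime,
                "f_prime": p.f_prime,
                "m_C": p.m_C,
                "d_C": p.d_C,
                "median": q50,
                "q25": q25,
                "q75": q75,
                "fractions": fracs,
            }
        )
    return pd.DataFrame(rows)
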