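"""Synthetic sexual-asexual complex fixtures.

Closes the loop between the simulators and the empirical pipeline: a
coalescent genealogy of clones plus sexual samples is simulated, standing
sexual polymorphism and post-formational (asexual-phase) mutations are
overlaid separately — the former weighted by the sexual portion of each
branch, the latter by the asexual portion — and the resulting binary
columns are encoded as nucleotides on a random ancestral sequence.  The
output mimics an empirical input dataset (aligned FASTA of one
mitochondrial locus plus a sample sheet), with a truth table recording
the phase of every variable column so pruning procedures can be scored.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .coalescent import CoalParams, run_coalescent
from .genealogy import Genealogy
from .overlay import HaplotypeMatrix, _branch_weights, _columns_from_assignment

__all__ = ["FixtureSpec", "ComplexFixture", "generate_complex_fixture"]

_BASES = np.array(list("ACGT"))


@dataclass
class FixtureSpec:
    coal: CoalParams = field(default_factory=lambda: CoalParams(
        L_C=4, N_C=2000, z_C=4, d_C=1, N_sex=2000, z_sex=4,
        hazard_mode="neutral", P_prime=2e-3,
    ))
    locus_length: int = 600
    sexual_S: int = 8          # standing sexual polymorphism sites
    asexual_S: int = 12        # post-formational sites
    complex_id: str = "synthetic_complex"
    seed: int = 0

    def validate(self) -> None:
        self.coal.validate()
        if self.coal.z_sex < 1:
            raise ValueError("fixtures need sexual samples (z_sex >= 1)")
        if self.sexual_S + self.asexual_S > self.locus_length:
            raise ValueError("more sites requested than locus length")


@dataclass
class ComplexFixture:
    genealogy: Genealogy
    fasta: str
    sample_sheet: str
    truth: str                 # TSV: position, phase (sexual/asexual)
    alignment_ids: list[str]
    matrix: HaplotypeMatrix    # combined binary matrix (all samples)
    phase: list[str]           # per-column phase labels


def _overlay_phase_weighted(
    g: Genealogy, S: int, phase: str, rng: np.random.Generator
) -> HaplotypeMatrix:
    """Overlay S sites weighted by the sexual or asexual portion of branches."""
    child_ids, w_total, desc = _branch_weights(g, "total")
    _, w_asex, _ = _branch_weights(g, "pruned")
    w = w_asex if phase == "asexual" else w_total - w_asex
    if S == 0:
        return HaplotypeMatrix(list(g.samples), np.zeros((len(g.samples), 0)))
    if w.sum() <= 0:
        raise ValueError(f"genealogy has no {phase}-phase branch length")
    counts = rng.multinomial(S, w / w.sum())
    return _columns_from_assignment(g, child_ids, counts, desc)


def generate_complex_fixture(spec: FixtureSpec) -> ComplexFixture:
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    g = run_coalescent(spec.coal, rng)

    m_sex = _overlay_phase_weighted(g, spec.sexual_S, "sexual", rng)
    m_asex = _overlay_phase_weighted(g, spec.asexual_S, "asexual", rng)
    data = np.concatenate([m_sex.data, m_asex.data], axis=1)
    phase = ["sexual"] * m_sex.S + ["asexual"] * m_asex.S
    samples = list(g.samples)
    matrix = HaplotypeMatrix(samples, data)

    # encode on a random ancestral sequence at distinct positions
    anc = rng.integers(0, 4, spec.locus_length)
    positions = np.sort(
        rng.choice(spec.locus_length, size=len(phase), replace=False)
    )
    derived = (anc[positions] + rng.integers(1, 4, len(phase))) % 4
    seq_rows = np.tile(anc, (len(samples), 1))
    for col, pos in enumerate(positions):
        seq_rows[data[:, col] == 1, pos] = derived[col]

    fasta = io.StringIO()
    sheet = io.StringIO()
    sheet.write("id\trole\tcluster\tcomplex\n")
    for i, sid in enumerate(samples):
        fasta.write(f">{sid}\n" + "".join(_BASES[seq_rows[i]]) + "\n")
        role = "sexual" if sid.startswith("s") else "asexual"
        cluster = g.nodes[sid].group or "unknown"
        sheet.write(f"{sid}\t{role}\t{cluster}\t{spec.complex_id}\n")
    truth = io.StringIO()
    truth.write("position\tphase\n")
    for pos, ph in zip(positions, phase):
        truth.write(f"{int(pos)}\t{ph}\n")

    return ComplexFixture(
        genealogy=g,
        fasta=fasta.getvalue(),
        sample_sheet=sheet.getvalue(),
        truth=truth.getvalue(),
        alignment_ids=samples,
        matrix=matrix,
        phase=phase,
    )
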