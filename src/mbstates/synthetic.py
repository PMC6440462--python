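"""Dirichlet-multinomial generators with planted latent states.

Each latent state is a Dirichlet composition profile whose signature-taxon
block is fold-enriched by ``separation``; samples draw a composition from
their state's Dirichlet and, at finite sequencing depth, multinomial counts
that are then total-sum scaled.  Ground-truth labels make every pipeline
stage testable without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import AbundanceTable

__all__ = ["SyntheticSpec", "LongitudinalSpec", "generate_states_dataset",
           "generate_longitudinal_dataset"]


@dataclass
class LongitudinalSpec:
    """Markov-chain layout for per-subject state sequences."""

    n_subjects: int
    timepoints: int
    transition: np.ndarray  # n_states x n_states row-stochastic
    initial: np.ndarray | None = None  # default uniform

    def validate(self, n_states: int) -> None:
        t = np.asarray(self.transition, dtype=float)
        if t.shape != (n_states, n_states):
            raise ValueError("transition matrix shape must be (n_states, n_states)")
        if np.any(t < 0) or not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must be non-negative and sum to 1")
        if self.initial is not None:
            p = np.asarray(self.initial, dtype=float)
            if p.shape != (n_states,) or np.any(p < 0) or abs(p.sum() - 1) > 1e-9:
                raise ValueError("initial distribution must be a length-n_states composition")


@dataclass
class SyntheticSpec:
    """Parameters of the planted-state generator."""

    n_states: int = 3
    samples_per_state: tuple[int, ...] | int = 40
    n_taxa: int = 100
    separation: float = 50.0
    signature_fraction: float = 0.1
    base_concentration: float = 1.0
    depth: int | None = 10_000  # None -> exact Dirichlet compositions
    overlapping_signatures: bool = False
    with_taxonomy: bool = False
    longitudinal: LongitudinalSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if isinstance(self.samples_per_state, int):
            self.samples_per_state = (self.samples_per_state,) * self.n_states
        self.samples_per_state = tuple(int(x) for x in self.samples_per_state)
        if len(self.samples_per_state) != self.n_states:
            raise ValueError("samples_per_state length must equal n_states")
        if any(x < 1 for x in self.samples_per_state):
            raise ValueError("samples_per_state entries must be positive")
        if self.separation < 0:
            raise ValueError("separation must be non-negative")
        if not 0 < self.signature_fraction <= 1:
            raise ValueError("signature_fraction must lie in (0, 1]")
        if self.longitudinal is not None:
            self.longitudinal.validate(self.n_states)

    @property
    def block_size(self) -> int:
        return max(1, int(round(self.signature_fraction * self.n_taxa)))


def _state_alphas(spec: SyntheticSpec) -> np.ndarray:
    """Per-state Dirichlet parameter vectors (n_states x n_taxa)."""
    b = spec.block_size
    if not spec.overlapping_signatures and spec.n_states * b > spec.n_taxa:
        raise ValueError(
            f"{spec.n_states} disjoint signature blocks of {b} taxa exceed "
            f"n_taxa={spec.n_taxa}")
    alphas = np.full((spec.n_states, spec.n_taxa),
                     float(spec.base_concentration))
    for s in range(spec.n_states):
        if spec.overlapping_signatures:
            start = (s * b // 2) % spec.n_taxa
        else:
            start = s * b
        idx = (np.arange(start, start + b)) % spec.n_taxa
        alphas[s, idx] *= 1.0 + spec.separation
    return alphas


def _default_taxonomy(taxon_ids, n_taxa: int) -> dict[str, tuple[str, ...]]:
    # pack taxa into genera of 5 so genus aggregation has structure to find
    tax = {}
    for j, tid in enumerate(taxon_ids):
        g = j // 5
        tax[tid] = (
            "k__Bacteria", f"p__P{g // 20}", f"c__C{g // 10}", f"o__O{g // 5}",
            f"f__F{g // 2}", f"g__G{g}", f"s__S{j}",
        )
    return tax


def _draw_samples(alphas: np.ndarray, labels: np.ndarray, depth,
                  rng: np.random.Generator) -> np.ndarray:
    n = len(labels)
    t = alphas.shape[1]
    values = np.empty((n, t))
    for i, s in enumerate(labels):
        comp = rng.dirichlet(alphas[s])
        if depth is not None:
            counts = rng.multinomial(int(depth), comp)
            while counts.sum() == 0:  # pragma: no cover - depth >= 1 given
                counts = rng.multinomial(int(depth), comp)
            comp = counts / counts.sum()
        values[i] = comp
    return values


def generate_states_dataset(spec: SyntheticSpec) -> tuple[AbundanceTable, np.ndarray]:
    """Generate a cross-sectional table with planted states.

    Returns the normalized table and the 0-based ground-truth state label of
    each sample.  Bit-reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    alphas = _state_alphas(spec)
    labels = np.repeat(np.arange(spec.n_states), spec.samples_per_state)
    values = _draw_samples(alphas, labels, spec.depth, rng)
    sample_ids = [f"S{i:04d}" for i in range(len(labels))]
    taxon_ids = [f"OTU{j:04d}" for j in range(spec.n_taxa)]
    taxonomy = _default_taxonomy(taxon_ids, spec.n_taxa) if spec.with_taxonomy else None
    metadata = {sid: {"state_truth": int(s)} for sid, s in zip(sample_ids, labels)}
    table = AbundanceTable(sample_ids=sample_ids, taxon_ids=taxon_ids,
                           values=values, taxonomy=taxonomy,
                           metadata=metadata, normalized=True)
    return table, labels


def generate_longitudinal_dataset(spec: SyntheticSpec) -> tuple[AbundanceTable, np.ndarray]:
    """Generate a multi-subject longitudinal table via a state Markov chain.

    Each subject's per-timepoint state follows ``spec.longitudinal``'s
    transition matrix; metadata carries ``subject_id`` and ``time_index``.
    """
    if spec.longitudinal is None:
        raise ValueError("spec.longitudinal is required")
    lon = spec.longitudinal
    rng = np.random.default_rng(spec.seed)
    alphas = _state_alphas(spec)
    transition = np.asarray(lon.transition, dtype=float)
    initial = (np.full(spec.n_states, 1.0 / spec.n_states)
               if lon.initial is None else np.asarray(lon.initial, dtype=float))

    labels = []
    sample_ids = []
    metadata = {}
    for subj in range(lon.n_subjects):
        state = int(rng.choice(spec.n_states, p=initial))
        for t in range(lon.timepoints):
            if t > 0:
                state = int(rng.choice(spec.n_states, p=transition[state]))
            sid = f"subj{subj:03d}_t{t:03d}"
            sample_ids.append(sid)
            labels.append(state)
            metadata[sid] = {"subject_id": f"subj{subj:03d}", "time_index": t,
                             "state_truth": state}
    labels = np.asarray(labels, dtype=int)
    values = _draw_samples(alphas, labels, spec.depth, rng)
    taxon_ids = [f"OTU{j:04d}" for j in range(spec.n_taxa)]
    taxonomy = _default_taxonomy(taxon_ids, spec.n_taxa) if spec.with_taxonomy else None
    table = AbundanceTable(sample_ids=sample_ids, taxon_ids=taxon_ids,
                           values=values, taxonomy=taxonomy,
                           metadata=metadata, normalized=True)
    return table, labels
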