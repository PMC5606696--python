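"""Seeded generators for every input the pipeline consumes.

Real enrichment data for this system would require months of reactor
operation plus cloning and sequencing, so the package ships generators that
emulate each data stream with the statistical structure the analysis
assumes:

* noisy rate-vs-concentration observations from known Haldane truth
  (multiplicative Gaussian noise — measured rates span decades over the
  concentration range, so errors scale with the signal);
* multinomial clone libraries drawn from a known clade composition, each
  clone being its clade's reference sequence with i.i.d. substitutions;
* weekly reactor cycle records whose aerobic phosphate removal follows a
  logistic enrichment curve (lag, growth, plateau) and whose anaerobic
  release and COD consumption follow fixed stoichiometric ratios.

The clade reference panel is itself synthetic: 300-nt "ppk1-like" sequences
built from a shared Type I ancestor, a diverged Type II ancestor, and
per-clade substitutions, preserving the discrimination structure the clade
assignment needs (clones are far closer to their own clade reference than to
any sibling clade, and within-type identities exceed between-type ones).

Everything is a pure function of (spec, seed): the same seed reproduces the
same data byte for byte.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np

from .balance import CycleRecord
from .community import CLADE_LABELS, CladeReferencePanel, CloneLibrary
from .competition import ReactorConfig
from .kinetics import REFERENCE_PARAMS, KineticParams, specific_rate

__all__ = [
    "SynthSpec",
    "ReactorTruth",
    "DEFAULT_COMPOSITION_TRUTH",
    "DEFAULT_CLONES_PER_RUN",
    "make_reference_panel",
    "gen_rate_observations",
    "gen_clone_library",
    "gen_reactor_timeseries",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: Clade probability vectors for the five default enrichment runs, chosen to
#: mirror the canonical pattern: mostly clade IA at very low and very high
#: phosphate, Type II clades (IIA/IIB) taking over in between, with IIB
#: dominating around 5 mg P L^-1.
DEFAULT_COMPOSITION_TRUTH: dict[str, dict[str, float]] = {
    "Run1": {"IA": 8 / 13, "IIA": 3 / 13, "IIB": 2 / 13},
    "Run2": {"IA": 5 / 13, "IIA": 4 / 13, "IIB": 4 / 13},
    "Run3": {"IIB": 20 / 24, "IIC": 2 / 24, "IID": 2 / 24},
    "Run4": {"IA": 19 / 20, "IIB": 1 / 20},
    "Run5": {"IA": 1.0},
}

#: Clones sequenced per run (libraries of 13-24 randomly picked clones).
DEFAULT_CLONES_PER_RUN: dict[str, int] = {
    "Run1": 13,
    "Run2": 13,
    "Run3": 24,
    "Run4": 20,
    "Run5": 14,
}


@dataclass(frozen=True)
class ReactorTruth:
    """Ground truth for the reactor time-series generator.

    The aerobic concentration drop ramps logistically from ~0 toward
    ``plateau_delta_p`` (mg P L^-1) with midpoint ``lag_days`` and rate
    ``growth_rate`` (d^-1), emulating gradual biofilm enrichment; release is
    ``release_uptake_ratio`` times uptake at steady state and each mg P
    released costs ``cod_per_p`` mg COD anaerobically.
    """

    config: ReactorConfig = field(
        default_factory=lambda: ReactorConfig(aerobic_s=50.0)
    )
    plateau_delta_p: float = 1.2
    lag_days: float = 40.0
    growth_rate: float = 0.15
    release_uptake_ratio: float = 1.0
    cod_per_p: float = 8.0
    aerobic_flow: float = 3.24
    anaerobic_fill_volume: float = 0.070
    anaerobic_influent_cod: float = 200.0
    sponge_volume: float = 6.0


@dataclass(frozen=True)
class SynthSpec:
    """Everything the generators need, plus the master seed."""

    seed: int = 0
    kinetics_truth: tuple[KineticParams, ...] = REFERENCE_PARAMS
    noise_sd: float = 0.01
    composition_truth: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION_TRUTH)
    )
    clones_per_run: Union[int, Mapping[str, int]] = field(
        default_factory=lambda: dict(DEFAULT_CLONES_PER_RUN)
    )
    mutation_rate: float = 0.005
    reactor_truth: ReactorTruth = field(default_factory=ReactorTruth)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.mutation_rate < 0.05):
            raise ValueError("mutation_rate must be in [0, 0.05)")
        for run_id, probs in self.composition_truth.items():
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{run_id}: clade probabilities sum to {total}")
            unknown = set(probs) - set(CLADE_LABELS)
            if unknown:
                raise ValueError(f"{run_id}: unknown clades {sorted(unknown)}")

    def n_clones(self, run_id: str) -> int:
        if isinstance(self.clones_per_run, int):
            return self.clones_per_run
        return self.clones_per_run[run_id]


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site independently with probability ``rate``.

    A mutated site always receives a *different* base, so ``rate`` is the
    realized per-site divergence in expectation.
    """
    out = seq.copy()
    hit = np.flatnonzero(rng.random(seq.size) < rate)
    for i in hit:
        choices = _BASES[_BASES != out[i]]
        out[i] = rng.choice(choices)
    return out


def _to_str(seq: np.ndarray) -> str:
    return seq.tobytes().decode()


#: Panel seed is fixed so the default panel is a stable, shareable reference.
DEFAULT_PANEL_SEED = 20170927


def make_reference_panel(
    seed: int = DEFAULT_PANEL_SEED,
    length: int = 300,
    type_divergence: float = 0.15,
    clade_divergence: tuple[float, float] = (0.04, 0.07),
) -> CladeReferencePanel:
    """Build a synthetic ppk1-like clade reference panel.

    One random ancestor per type (Type II diverged from Type I at
    ``type_divergence`` per site), then one reference per clade diverged from
    its type ancestor at a rate drawn uniformly from ``clade_divergence``.
    The defaults give within-type reference identities of roughly 0.85-0.92
    and between-type identities of roughly 0.70-0.80 — comfortably separable
    at the default assignment threshold while realistic for a single marker
    gene.
    """
    rng = np.random.default_rng(seed)
    ancestor_i = rng.choice(_BASES, size=length)
    ancestor_ii = _mutate(ancestor_i, type_divergence, rng)
    entries = []
    for clade in CLADE_LABELS:
        ancestor = ancestor_ii if clade.startswith("II") else ancestor_i
        rate = rng.uniform(*clade_divergence)
        entries.append((clade, _to_str(_mutate(ancestor, rate, rng))))
    return CladeReferencePanel(entries=tuple(entries))


def gen_rate_observations(
    spec: SynthSpec,
    n_per_type: int = 50,
    s_range: tuple[float, float] = (0.01, 1000.0),
) -> dict[str, list[tuple[float, float]]]:
    """Noisy rate observations on a log-spaced concentration grid, per type.

    rate = nu_truth(s) * (1 + eps), eps ~ Normal(0, noise_sd), i.i.d.
    """
    rng = np.random.default_rng(spec.seed)
    grid = np.geomspace(s_range[0], s_range[1], n_per_type)
    out: dict[str, list[tuple[float, float]]] = {}
    for params in spec.kinetics_truth:
        truth = specific_rate(params, grid)
        eps = rng.normal(0.0, spec.noise_sd, size=grid.size) if spec.noise_sd else 0.0
        noisy = truth * (1.0 + eps)
        out[params.label] = list(zip(grid.tolist(), np.asarray(noisy).tolist()))
    return out


def gen_clone_library(
    spec: SynthSpec,
    run_id: str,
    panel: CladeReferencePanel | None = None,
) -> tuple[CloneLibrary, dict[str, str], dict[str, int]]:
    """Draw one run's clone library from its true clade composition.

    Clade counts are Multinomial(n_clones, composition_truth[run_id]); each
    clone is its clade's reference sequence with i.i.d. substitutions at
    ``mutation_rate``.  Returns ``(library, truth labels per clone, sampled
    counts per clade)`` so downstream recovery can be checked exactly.
    """
    if panel is None:
        panel = make_reference_panel()
    probs = spec.composition_truth[run_id]
    panel_seqs = dict(panel.entries)
    missing = [c for c in probs if probs[c] > 0 and c not in panel_seqs]
    if missing:
        raise ValueError(f"clades missing from panel: {missing}")
    # independent substream per run so libraries do not share randomness
    # (crc32, not hash(): the latter is salted per process)
    rng = np.random.default_rng([spec.seed, zlib.crc32(run_id.encode()) % 2**31])
    clades = list(probs)
    n = spec.n_clones(run_id)
    counts = rng.multinomial(n, [probs[c] for c in clades])
    sequences: list[tuple[str, str]] = []
    truth: dict[str, str] = {}
    clone_no = 0
    for clade, count in zip(clades, counts):
        ref = np.frombuffer(panel_seqs[clade].encode(), dtype="S1")
        for _ in range(count):
            clone_no += 1
            cid = f"{run_id}_clone{clone_no:02d}"
            sequences.append((cid, _to_str(_mutate(ref, spec.mutation_rate, rng))))
            truth[cid] = clade
    # shuffle clone order so clustering sees no clade blocks
    order = rng.permutation(len(sequences))
    sequences = [sequences[i] for i in order]
    library = CloneLibrary(run_id=run_id, sequences=tuple(sequences))
    sampled = {c: int(k) for c, k in zip(clades, counts) if k > 0}
    return library, truth, sampled


def gen_reactor_timeseries(
    spec: SynthSpec,
    n_days: int = 85,
    sampling_interval_days: int = 7,
) -> list[CycleRecord]:
    """Weekly cycle records tracing a logistic enrichment curve.

    The aerobic concentration drop at day ``d`` is
    ``plateau / (1 + exp(-rate * (d - lag)))``; the anaerobic end-of-phase
    concentrations are back-computed so the implied release equals
    ``release_uptake_ratio`` x uptake (x multiplicative noise) and COD
    consumption equals ``cod_per_p`` x release, capped by the available COD.
    """
    if n_days < sampling_interval_days:
        raise ValueError("n_days must cover at least one sampling interval")
    truth = spec.reactor_truth
    rng = np.random.default_rng([spec.seed, 7])
    influent = truth.config.aerobic_s
    records: list[CycleRecord] = []
    days = range(sampling_interval_days, n_days + 1, sampling_interval_days)
    for day in days:
        logistic = 1.0 / (1.0 + np.exp(-truth.growth_rate * (day - truth.lag_days)))
        delta = truth.plateau_delta_p * logistic
        delta = min(delta, influent)
        effluent = influent - delta
        uptake = truth.aerobic_flow * (truth.config.aerobic_hours / 24.0) * delta
        noise = 1.0 + (rng.normal(0.0, spec.noise_sd) if spec.noise_sd else 0.0)
        release = max(truth.release_uptake_ratio * uptake * noise, 0.0)
        retained = truth.sponge_volume / 1000.0
        end_p = (release + retained * effluent) / truth.anaerobic_fill_volume
        cod_used = min(
            truth.cod_per_p * release,
            truth.anaerobic_influent_cod * truth.anaerobic_fill_volume,
        )
        end_cod = max(
            truth.anaerobic_influent_cod
            - cod_used / truth.anaerobic_fill_volume,
            0.0,
        )
        records.append(
            CycleRecord(
                run_id="synthetic",
                day=float(day),
                aerobic_influent_p=float(influent),
                aerobic_effluent_p=float(effluent),
                anaerobic_end_p=float(end_p),
                anaerobic_end_cod=float(end_cod),
                aerobic_flow=truth.aerobic_flow,
                aerobic_hours=truth.config.aerobic_hours,
                anaerobic_hours=truth.config.anaerobic_hours,
                anaerobic_fill_volume=truth.anaerobic_fill_volume,
                anaerobic_influent_cod=truth.anaerobic_influent_cod,
                sponge_volume=truth.sponge_volume,
                retained_liquid_volume=retained,
            )
        )
    return records
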