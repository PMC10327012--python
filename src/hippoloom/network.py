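"""Instantiate spiking networks from a knowledge base.

Populations are sized from the census (optionally scaled down), laid out on
contiguous global neuron indices, and wired pair-by-pair with independent
Bernoulli draws at the knowledge base's connection probability.  Every
directed type pair draws from its own random substream derived from the
master seed and the two type names, so adding or removing a population
never perturbs another pair's edges.

Contacts per connected pair enter as a per-edge conductance multiplier
(identical mean postsynaptic drive to explicit multi-edges, at lower
memory).  Per-edge delays default to uniform 1-2 ms.
"""

from __future__ import annotations

import csv
import zlib
from dataclasses import dataclass
from pathlib import Path
import numpy as np

from .knowledge import (KnowledgeBase, IzhikevichParams, TPMParams, _check)


def round_half_up(x: float) -> int:
    """Round with ties away from zero toward +inf (0.5 -> 1, 1.5 -> 2)."""
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class Population:
    """A neuron type instantiated as ``size`` neurons on global indices
    ``first_index .. first_index + size - 1``."""

    type_name: str
    size: int
    first_index: int

    def __post_init__(self) -> None:
        _check(self.size >= 1, f"population {self.type_name} must have size >= 1")

    @property
    def index_range(self) -> range:
        return range(self.first_index, self.first_index + self.size)


@dataclass
class DelayModel:
    """Synaptic delay distribution (ms): constant, or uniform on [lo, hi]."""

    kind: str = "uniform"
    lo: float = 1.0
    hi: float = 2.0

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "constant":
            return np.full(n, self.lo)
        if self.kind == "uniform":
            return rng.uniform(self.lo, self.hi, size=n)
        raise ValueError(f"unknown delay model {self.kind!r}")


@dataclass
class SynapseGroup:
    """All edges of one directed type pair, with shared TPM parameters.

    ``weight_scale`` multiplies the unitary conductance per edge (used to
    fold in contacts per connected pair); ``delays`` are per-edge in ms.
    """

    pre: str
    post: str
    pre_indices: np.ndarray    # global indices, one per edge
    post_indices: np.ndarray
    weight_scale: np.ndarray   # per-edge conductance multiplier
    delays: np.ndarray         # per-edge delay, ms
    tpm: TPMParams

    @property
    def n_edges(self) -> int:
        return int(self.pre_indices.size)


@dataclass
class NetworkSpec:
    """A fully instantiated network ready to simulate."""

    populations: list[Population]
    groups: list[SynapseGroup]
    izhikevich: dict[str, IzhikevichParams]
    polarity: dict[str, str]
    master_seed: int
    scale: float = 1.0

    @property
    def n_neurons(self) -> int:
        return sum(p.size for p in self.populations)

    def population(self, name: str) -> Population:
        for p in self.populations:
            if p.type_name == name:
                return p
        raise KeyError(name)


def _pair_rng(master_seed: int, pre: str, post: str, salt: int = 0) -> np.random.Generator:
    """Independent substream for one directed pair (stable across runs)."""
    entropy = [int(master_seed), zlib.crc32(pre.encode()),
               zlib.crc32(post.encode()), salt]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def build_populations(kb: KnowledgeBase, scale: float = 1.0) -> list[Population]:
    """Size populations as ``max(1, round_half_up(scale * count))`` on
    contiguous, gapless global indices (type-name order of the census)."""
    _check(0.0 < scale <= 1.0, f"scale {scale} outside (0, 1]")
    missing = [nm for nm in kb.neuron_types if nm not in kb.census]
    _check(not missing, f"census missing for {missing}")
    pops = []
    first = 0
    for nm in kb.neuron_types:
        size = max(1, round_half_up(scale * kb.census[nm].count))
        pops.append(Population(type_name=nm, size=size, first_index=first))
        first += size
    return pops


def wire(pre: Population, post: Population, probability: float,
         rng_seed: int | np.random.Generator) -> np.ndarray:
    """Draw a Bernoulli edge list between two populations.

    Returns an (n_edges, 2) array of global (pre, post) indices.  Every
    ordered pair is included independently with the given probability;
    self-edges are excluded when the two populations are the same one.
    Equivalent to elementwise Bernoulli sampling: the edge count is drawn
    Binomial(M, p) and that many distinct pair slots are chosen uniformly.
    """
    _check(0.0 <= probability <= 1.0, f"probability {probability} outside [0, 1]")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    recurrent = pre.first_index == post.first_index and pre.size == post.size
    n_pre, n_post = pre.size, post.size
    m = n_pre * (n_post - 1) if recurrent else n_pre * n_post
    if m == 0 or probability == 0.0:
        return np.empty((0, 2), dtype=np.int64)
    k = int(rng.binomial(m, probability))
    if k == 0:
        return np.empty((0, 2), dtype=np.int64)
    slots = np.sort(rng.choice(m, size=k, replace=False))
    if recurrent:
        i = slots // (n_post - 1)
        r = slots % (n_post - 1)
        j = r + (r >= i)
    else:
        i = slots // n_post
        j = slots % n_post
    return np.column_stack([i + pre.first_index, j + post.first_index])


def assign_synapses(edges: np.ndarray, tpm: TPMParams,
                    delay_model: DelayModel | None = None,
                    rng_seed: int | np.random.Generator = 0,
                    weight_scale: float = 1.0,
                    pre: str = "", post: str = "") -> SynapseGroup:
    """Attach shared TPM parameters and per-edge delays/weights to an edge list."""
    if tpm is None:
        raise ValueError(f"no TPM parameters for pair ({pre!r}, {post!r}); "
                         "run fill_missing_synapses first")
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    dm = delay_model or DelayModel()
    return SynapseGroup(
        pre=pre, post=post,
        pre_indices=edges[:, 0].copy(), post_indices=edges[:, 1].copy(),
        weight_scale=np.full(edges.shape[0], float(weight_scale)),
        delays=dm.draw(edges.shape[0], rng), tpm=tpm)


def build_network(kb: KnowledgeBase, scale: float = 1.0, seed: int = 0,
                  delay_model: DelayModel | None = None) -> NetworkSpec:
    """Instantiate one population per type and one synapse group per
    positive-probability connection row.

    The knowledge base must be complete (after default fill-in): every type
    needs census and Izhikevich rows, every wired pair TPM parameters.
    """
    kb.validate()
    pops = build_populations(kb, scale)
    by_name = {p.type_name: p for p in pops}
    missing_iz = [nm for nm in kb.neuron_types if nm not in kb.izhikevich]
    _check(not missing_iz, f"izhikevich parameters missing for {missing_iz}")

    groups = []
    for (pre_nm, post_nm), conn in sorted(kb.connections.items()):
        if conn.probability <= 0.0:
            continue
        tpm = kb.synapses.get((pre_nm, post_nm))
        if tpm is None:
            raise ValueError(
                f"no TPM parameters for pair ({pre_nm!r}, {post_nm!r}); "
                "run fill_missing_synapses first")
        edges = wire(by_name[pre_nm], by_name[post_nm], conn.probability,
                     _pair_rng(seed, pre_nm, post_nm, salt=1))
        groups.append(assign_synapses(
            edges, tpm, delay_model,
            rng_seed=_pair_rng(seed, pre_nm, post_nm, salt=2),
            weight_scale=conn.contacts, pre=pre_nm, post=post_nm))

    return NetworkSpec(
        populations=pops, groups=groups,
        izhikevich={nm: kb.izhikevich[nm] for nm in kb.neuron_types},
        polarity={nm: t.polarity for nm, t in kb.neuron_types.items()},
        master_seed=seed, scale=scale)


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

def export_network(net: NetworkSpec, destination: str | Path) -> dict[str, Path]:
    """Write populations.csv and edges.csv; deterministic byte-for-byte
    for identical (kb, scale, seed)."""
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    pop_path = dest / "populations.csv"
    with open(pop_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "size", "first_index"])
        for p in net.populations:
            w.writerow([p.type_name, p.size, p.first_index])
    edge_path = dest / "edges.csv"
    with open(edge_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["pre_index", "post_index", "group", "delay_ms", "weight_scale"])
        for gi, g in enumerate(net.groups):
            for e in range(g.n_edges):
                w.writerow([int(g.pre_indices[e]), int(g.post_indices[e]), gi,
                            repr(float(g.delays[e])),
                            repr(float(g.weight_scale[e]))])
    return {"populations.csv": pop_path, "edges.csv": edge_path}


def load_network(source: str | Path, kb: KnowledgeBase) -> NetworkSpec:
    """Re-import an exported network (losslessly) against its knowledge base."""
    src = Path(source)
    pops = []
    with open(src / "populations.csv", newline="", encoding="utf-8") as fh:
        for rec in csv.DictReader(fh):
            pops.append(Population(type_name=rec["name"], size=int(rec["size"]),
                                   first_index=int(rec["first_index"])))
    group_names = [(pre, post) for (pre, post), c in sorted(kb.connections.items())
                   if c.probability > 0.0]
    rows: dict[int, list[tuple[int, int, float, float]]] = {}
    with open(src / "edges.csv", newline="", encoding="utf-8") as fh:
        for rec in csv.DictReader(fh):
            rows.setdefault(int(rec["group"]), []).append(
                (int(rec["pre_index"]), int(rec["post_index"]),
                 float(rec["delay_ms"]), float(rec["weight_scale"])))
    groups = []
    for gi, (pre_nm, post_nm) in enumerate(group_names):
        data = rows.get(gi, [])
        arr = np.asarray(data, dtype=float).reshape(-1, 4)
        groups.append(SynapseGroup(
            pre=pre_nm, post=post_nm,
            pre_indices=arr[:, 0].astype(np.int64),
            post_indices=arr[:, 1].astype(np.int64),
            weight_scale=arr[:, 3].copy(), delays=arr[:, 2].copy(),
            tpm=kb.synapses[(pre_nm, post_nm)]))
    return NetworkSpec(
        populations=pops, groups=groups,
        izhikevich={nm: kb.izhikevich[nm] for nm in kb.neuron_types},
        polarity={nm: t.polarity for nm, t in kb.neuron_types.items()},
        master_seed=-1)
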