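"""Synthetic knowledge bases and worked-example scenarios.

Everything here is generated programmatically and deterministically per
seed.  Fixture Izhikevich/TPM/census values are package-defined,
physiologically plausible magnitudes (resting potentials -50..-85 mV,
conductances of order 1 nS, time constants of milliseconds to seconds);
they are fixtures, not measured hippocampal parameters.  The exception is
the mossy-fiber scenario, which encodes the published anatomical constants
for dentate granule cell axons in CA3 (axonal length and inter-bouton
distances) together with synthetic placeholder volumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .connectivity import ParcelGeometry, write_parcels
from .knowledge import (CensusEntry, ConnectionEntry, IzhikevichParams,
                        KnowledgeBase, NeuronType, TPMParams,
                        connection_class, export_knowledge_base)

#: The eight neuron types of the CA3-like demo circuit: one excitatory
#: pyramidal population plus the seven main inhibitory interneuron types.
CA3_DEMO_TYPES = (
    "CA3 Pyramidal",
    "CA3 Axo-Axonic",
    "CA3 Basket",
    "CA3 Basket CCK+",
    "CA3 Bistratified",
    "CA3 Ivy",
    "CA3 Mossy Fiber-Associated ORDEN",
    "CA3 QuadD-LM",
)

#: Published anatomical constants for the granule-cell mossy fiber scenario.
MOSSY_FIBER_AXONAL_LENGTH_UM = 3236.0
MOSSY_FIBER_IBD_UM = {
    "pyramidal_CA3c": 162.0,
    "pyramidal_CA3": 284.0,
    "interneuron": 67.4,
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a randomized fixture knowledge base."""

    n_types: int = 4
    species: str = "mouse"
    seed: int = 0
    completeness: float = 1.0  # fraction of connection rows present

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness <= 1.0:
            raise ValueError("completeness must be in [0, 1]")
        if self.n_types < 1:
            raise ValueError("need at least one type")


def _rs_params(rng: np.random.Generator) -> IzhikevichParams:
    """Regular-spiking (pyramidal-like) constants with mild jitter."""
    return IzhikevichParams(
        C=float(rng.uniform(90, 130)), k=float(rng.uniform(0.6, 0.9)),
        Vr=float(rng.uniform(-65, -58)), Vt=float(rng.uniform(-44, -38)),
        Vpeak=35.0, Vmin=float(rng.uniform(-55, -48)),
        a=float(rng.uniform(0.02, 0.04)), b=float(rng.uniform(-3, 1)),
        d=float(rng.uniform(60, 140)))


def _fs_params(rng: np.random.Generator) -> IzhikevichParams:
    """Fast-spiking (interneuron-like) constants with mild jitter."""
    return IzhikevichParams(
        C=float(rng.uniform(18, 40)), k=float(rng.uniform(0.9, 1.3)),
        Vr=float(rng.uniform(-62, -54)), Vt=float(rng.uniform(-44, -38)),
        Vpeak=25.0, Vmin=float(rng.uniform(-50, -44)),
        a=float(rng.uniform(0.1, 0.25)), b=float(rng.uniform(0.5, 3.0)),
        d=float(rng.uniform(10, 60)))


def _tpm_params(rng: np.random.Generator, pre_polarity: str) -> TPMParams:
    if pre_polarity == "excitatory":
        return TPMParams(g=float(rng.uniform(0.5, 1.2)),
                         tau_d=float(rng.uniform(3, 6)),
                         tau_r=float(rng.uniform(250, 500)),
                         tau_f=float(rng.uniform(10, 60)),
                         U=float(rng.uniform(0.35, 0.6)))
    return TPMParams(g=float(rng.uniform(1.0, 2.5)),
                     tau_d=float(rng.uniform(5, 9)),
                     tau_r=float(rng.uniform(300, 700)),
                     tau_f=float(rng.uniform(15, 80)),
                     U=float(rng.uniform(0.25, 0.5)))


_CLASS_P = {"EE": 0.01, "EI": 0.02, "IE": 0.01, "II": 0.005}


def make_toy_circuit(seed: int = 0, out_dir: str | Path | None = None) -> KnowledgeBase:
    """A complete 4-type toy circuit: 2 excitatory + 2 inhibitory types in
    DG and CA3, all 12 non-self directed connection rows present."""
    rng = np.random.default_rng(seed)
    spec = [("DG Toy Granule", "DG", "excitatory", 1, "0232p"),
            ("DG Toy Basket", "DG", "inhibitory", 2, "0131"),
            ("CA3 Toy Pyramidal", "CA3", "excitatory", 1, "23331p"),
            ("CA3 Toy Basket", "CA3", "inhibitory", 2, "00131")]
    kb = KnowledgeBase()
    for name, sub, pol, rank, code in spec:
        kb.neuron_types[name] = NeuronType(name, sub, pol, rank, code)
        kb.census[name] = CensusEntry(name, "mouse",
                                      int(rng.integers(500, 5000)))
        kb.izhikevich[name] = (_rs_params(rng) if pol == "excitatory"
                               else _fs_params(rng))
    for pre in kb.neuron_types:
        for post in kb.neuron_types:
            if pre == post:
                continue
            cls = connection_class(kb.polarity(pre), kb.polarity(post))
            p = _CLASS_P[cls] * float(rng.uniform(0.5, 2.0))
            kb.connections[(pre, post)] = ConnectionEntry(
                pre, post, probability=min(1.0, p),
                contacts=float(rng.uniform(1.0, 3.0)))
            kb.synapses[(pre, post)] = _tpm_params(rng, kb.polarity(pre))
    kb.validate()
    if out_dir is not None:
        export_knowledge_base(kb, out_dir)
    return kb


#: Fixture census counts for the CA3-like demo (mouse, package-defined).
_CA3_CENSUS = {
    "CA3 Pyramidal": 74000,
    "CA3 Axo-Axonic": 1500,
    "CA3 Basket": 5000,
    "CA3 Basket CCK+": 3600,
    "CA3 Bistratified": 2200,
    "CA3 Ivy": 8900,
    "CA3 Mossy Fiber-Associated ORDEN": 4000,
    "CA3 QuadD-LM": 1800,
}


def make_ca3_demo(scale: float = 1.0, seed: int = 0,
                  out_dir: str | Path | None = None) -> KnowledgeBase:
    """The CA3-like demo circuit: one excitatory pyramidal type plus seven
    inhibitory interneuron types, with complete fixture tables.

    ``scale`` is not applied here (population scaling happens at network
    build time); it is validated for interface symmetry with the builder.
    """
    if not 0.0 < scale <= 1.0:
        raise ValueError(f"scale {scale} outside (0, 1]")
    rng = np.random.default_rng(seed)
    kb = KnowledgeBase()
    for i, name in enumerate(CA3_DEMO_TYPES):
        pol = "excitatory" if name == "CA3 Pyramidal" else "inhibitory"
        rank = 1 if name in ("CA3 Pyramidal", "CA3 Basket") else 2
        code = "23331p" if pol == "excitatory" else "0013" + str((i % 3) + 1)
        kb.neuron_types[name] = NeuronType(name, "CA3", pol, rank, code)
        kb.census[name] = CensusEntry(name, "mouse", _CA3_CENSUS[name])
        kb.izhikevich[name] = (_rs_params(rng) if pol == "excitatory"
                               else _fs_params(rng))
    for pre in kb.neuron_types:
        for post in kb.neuron_types:
            cls = connection_class(kb.polarity(pre), kb.polarity(post))
            p = _CLASS_P[cls] * float(rng.uniform(0.7, 1.4))
            kb.connections[(pre, post)] = ConnectionEntry(
                pre, post, probability=min(1.0, p),
                contacts=float(rng.uniform(1.0, 2.5)))
            kb.synapses[(pre, post)] = _tpm_params(rng, kb.polarity(pre))
    kb.validate()
    if out_dir is not None:
        export_knowledge_base(kb, out_dir)
    return kb


def make_incomplete_kb(completeness: float, seed: int = 0,
                       out_dir: str | Path | None = None) -> KnowledgeBase:
    """The toy circuit with a known fraction of connection rows removed,
    for exercising default fill-in.  ``completeness=1`` keeps all rows;
    ``completeness=0`` removes them all."""
    if not 0.0 <= completeness <= 1.0:
        raise ValueError("completeness must be in [0, 1]")
    kb = make_toy_circuit(seed)
    pairs = sorted(kb.connections)
    n_keep = int(round(completeness * len(pairs)))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF1]))
    keep = {pairs[i] for i in rng.choice(len(pairs), size=n_keep, replace=False)}
    kb.connections = {pr: c for pr, c in kb.connections.items() if pr in keep}
    kb.validate()
    if out_dir is not None:
        export_knowledge_base(kb, out_dir)
    return kb


def make_random_kb(spec: FixtureSpec) -> KnowledgeBase:
    """A randomized but always-valid knowledge base for property tests."""
    rng = np.random.default_rng(spec.seed)
    subs = ("DG", "CA3", "CA2", "CA1", "Sub", "EC")
    kb = KnowledgeBase()
    for i in range(spec.n_types):
        pol = "excitatory" if rng.random() < 0.5 else "inhibitory"
        sub = subs[int(rng.integers(len(subs)))]
        code = "".join(str(int(rng.integers(4))) for _ in range(4))
        code += "p" if rng.random() < 0.3 else ""
        name = f"{sub} Synth{i}"
        kb.neuron_types[name] = NeuronType(
            name, sub, pol, int(rng.integers(1, 6)), code)
        kb.census[name] = CensusEntry(name, spec.species,
                                      int(rng.integers(1, 10000)))
        kb.izhikevich[name] = (_rs_params(rng) if pol == "excitatory"
                               else _fs_params(rng))
    names = list(kb.neuron_types)
    for pre in names:
        for post in names:
            if rng.random() > spec.completeness:
                continue
            cls = connection_class(kb.polarity(pre), kb.polarity(post))
            kb.connections[(pre, post)] = ConnectionEntry(
                pre, post,
                probability=min(1.0, _CLASS_P[cls] * float(rng.uniform(0, 3))),
                contacts=float(rng.uniform(1.0, 4.0)))
            kb.synapses[(pre, post)] = _tpm_params(rng, kb.polarity(pre))
    return kb.validate()


def make_mossy_fiber_scenario(out_path: str | Path | None = None,
                              ) -> list[ParcelGeometry]:
    """The granule-cell mossy-fiber worked scenario as parcel rows.

    Encodes the published constants: 3,236 µm of granule-cell axon in CA3,
    inter-bouton distances of 162 µm (pyramidal targets in CA3c), 284 µm
    (pyramidal targets in the rest of CA3) and 67.4 µm (interneuron
    targets), with innervation restricted to stratum lucidum (SL): all
    non-SL parcels carry zero axonal length.  Volumes and dendritic lengths
    are synthetic placeholders (the published per-parcel hull volumes are
    not part of this package) and are flagged by the ``synthetic`` prefix
    of their parcel ids' scenario file.
    """
    la = MOSSY_FIBER_AXONAL_LENGTH_UM
    placeholder_volume = 2.0e8   # µm³, synthetic placeholder
    placeholder_dendrite = 3000.0  # µm, synthetic placeholder
    parcels = [
        ParcelGeometry("CA3c:SL:pyramidal", placeholder_volume, la,
                       placeholder_dendrite, MOSSY_FIBER_IBD_UM["pyramidal_CA3c"]),
        ParcelGeometry("CA3:SL:pyramidal", placeholder_volume, la,
                       placeholder_dendrite, MOSSY_FIBER_IBD_UM["pyramidal_CA3"]),
        ParcelGeometry("CA3:SL:interneuron", placeholder_volume, la,
                       placeholder_dendrite, MOSSY_FIBER_IBD_UM["interneuron"]),
        ParcelGeometry("CA3:SP:interneuron", placeholder_volume, 0.0,
                       placeholder_dendrite, MOSSY_FIBER_IBD_UM["interneuron"]),
        ParcelGeometry("CA3:SO:pyramidal", placeholder_volume, 0.0,
                       placeholder_dendrite, MOSSY_FIBER_IBD_UM["pyramidal_CA3"]),
    ]
    if out_path is not None:
        write_parcels(parcels, out_path)
    return parcels
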