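"""Potential connectivity from axonal-dendritic overlap.

Potential connectivity infers synaptic contact from the spatial
co-occurrence of presynaptic axons and postsynaptic dendrites in a parcel
(one layer of one subregion, e.g. CA3 stratum lucidum, ``"CA3:SL"``),
without paired recordings.  The ingredients per parcel are:

* ``La`` — presynaptic axonal length inside the parcel (µm),
* ``ibd`` — mean inter-bouton distance along that axon (µm), so the axon
  carries ``Nb = La / ibd`` boutons in the parcel,
* ``Ld`` — one postsynaptic neuron's dendritic length in the parcel (µm),
* ``V`` — parcel volume (µm³, convex hull),
* ``r`` — interaction radius (µm): a bouton within distance r of a dendrite
  can form a contact.

Each bouton independently "hits" the target dendrite with probability
``q = min(1, Ld * pi * r^2 / V)`` (the dendrite's interaction cylinder as a
volume fraction of the parcel).  Summing over parcels k:

* expected synapses per directed pair:  ``lambda = sum_k Nb_k * q_k``
* connection probability:               ``p = 1 - prod_k (1 - q_k)^Nb_k``
* contacts per connected pair:          ``c = lambda / p`` (for p > 0)

so ``c`` is the conditional expectation of the synapse count given at least
one contact, and ``c -> 1`` as ``lambda -> 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .knowledge import KnowledgeBase, TableError, _check

#: Default interaction radius (µm): order of bouton plus spine reach.
DEFAULT_INTERACTION_RADIUS = 1.0


@dataclass(frozen=True)
class ParcelGeometry:
    """Geometry of one axonal-dendritic overlap parcel."""

    parcel_id: str
    volume: float                # µm³ (convex hull)
    axonal_length: float         # µm of presynaptic axon in parcel (La)
    dendritic_length: float      # µm of one target's dendrite in parcel (Ld)
    interbouton_distance: float  # µm (ibd)
    interaction_radius: float = DEFAULT_INTERACTION_RADIUS  # µm (r)

    def __post_init__(self) -> None:
        _check(self.volume > 0, f"{self.parcel_id}: volume must be positive")
        _check(self.axonal_length >= 0 and self.dendritic_length >= 0,
               f"{self.parcel_id}: lengths must be non-negative")
        _check(self.interbouton_distance > 0,
               f"{self.parcel_id}: inter-bouton distance must be positive")
        _check(self.interaction_radius > 0,
               f"{self.parcel_id}: interaction radius must be positive")


@dataclass(frozen=True)
class ConnectivityEstimate:
    """Closed-form potential-connectivity summary for one directed pair."""

    expected_synapses: float   # lambda, >= 0
    probability: float         # p in [0, 1]
    contacts: float | None     # lambda / p, None when p == 0


def bouton_count(axonal_length: float, interbouton_distance: float) -> float:
    """Number of boutons on an axon: length divided by inter-bouton distance.

    E.g. a granule-cell axon of 3,236 µm with 67.4 µm between boutons onto
    interneurons carries ~48 boutons, i.e. can contact 48 interneurons.
    """
    if interbouton_distance <= 0:
        raise ValueError("inter-bouton distance must be positive")
    if axonal_length < 0:
        raise ValueError("axonal length must be non-negative")
    return axonal_length / interbouton_distance


def partition_axonal_length(total_length: float,
                            region_fraction: float,
                            layer_fractions: Mapping[str, float]) -> dict[str, float]:
    """Split a total axonal length into per-layer lengths.

    ``region_fraction`` is the fraction of the total axon entering the target
    region; ``layer_fractions`` distributes that portion over layers and must
    sum to 1 (±1e-9).  Example (Schaffer collaterals from CA3 Pyramidal
    cells): 27.5% of the axon reaches CA1, split 64% SR / 15% SP / 21% SO.
    """
    if not 0.0 <= region_fraction <= 1.0:
        raise ValueError(f"region fraction {region_fraction} outside [0, 1]")
    for layer, f in layer_fractions.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"layer fraction {layer}={f} outside [0, 1]")
    total_f = sum(layer_fractions.values())
    if abs(total_f - 1.0) > 1e-9:
        raise ValueError(f"layer fractions sum to {total_f}, expected 1")
    return {layer: total_length * region_fraction * f
            for layer, f in layer_fractions.items()}


def mean_interbouton_distance(values: Sequence[float]) -> float:
    """Arithmetic mean of inter-bouton distances (µm).

    Display convention is 0.1 µm resolution: mean(3.7, 4.4, 4.29) = 4.13,
    reported as 4.1.
    """
    vals = list(values)
    if not vals:
        raise ValueError("need at least one inter-bouton distance")
    if any(v <= 0 for v in vals):
        raise ValueError("inter-bouton distances must be positive")
    return sum(vals) / len(vals)


def pair_hit_probability(geometry: ParcelGeometry) -> float:
    """Probability one bouton lands in the target dendrite's interaction
    cylinder in the parcel: ``q = min(1, Ld * pi * r^2 / V)``."""
    q = (geometry.dendritic_length * math.pi * geometry.interaction_radius ** 2
         / geometry.volume)
    return min(1.0, q)


def estimate_connection(parcels: Iterable[ParcelGeometry]) -> ConnectivityEstimate:
    """Closed-form (lambda, p, contacts) for one directed pair over parcels.

    Bouton placements are independent, so the miss probability multiplies
    across parcels with exponent equal to the (real-valued) bouton count.
    ``contacts`` is None when p == 0: the conditional expectation is
    undefined for a pair that can never connect.
    """
    parcels = list(parcels)
    if not parcels:
        raise ValueError("need at least one parcel")
    lam = 0.0
    log_miss = 0.0
    saturated = False
    for g in parcels:
        nb = bouton_count(g.axonal_length, g.interbouton_distance)
        q = pair_hit_probability(g)
        lam += nb * q
        if nb <= 0.0 or q <= 0.0:
            continue
        if q >= 1.0:
            saturated = True
        else:
            log_miss += nb * math.log1p(-q)
    p = 1.0 if saturated else -math.expm1(log_miss)
    contacts = (lam / p) if p > 0 else None
    return ConnectivityEstimate(expected_synapses=lam, probability=p,
                                contacts=contacts)


def transfer_function(g: float, tau_d: float) -> float:
    """Synaptic transfer strength: conductance times decay time (nS·ms).

    Proportional to the charge transferred by one unitary event through a
    single-exponential synapse.
    """
    if g <= 0 or tau_d <= 0:
        raise ValueError("g and tau_d must be positive")
    return g * tau_d


def aggregate_connectivity(kb: KnowledgeBase, level: str = "type") -> nx.DiGraph:
    """Summarize the connection table as a directed graph.

    * ``"subregion"``: nodes are subregions; edge weight = number of directed
      type-pairs connecting them (probability > 0).
    * ``"type"``: nodes are neuron types; one edge per connection row with
      probability > 0, weighted by probability.
    * ``"pair"``: like "type" but nodes restricted to types that appear in at
      least one positive-probability row.
    """
    if level not in ("subregion", "type", "pair"):
        raise ValueError(f"unknown aggregation level {level!r}")
    g = nx.DiGraph()
    rows = [c for c in kb.connections.values() if c.probability > 0]
    if level == "subregion":
        g.add_nodes_from(sorted({t.subregion for t in kb.neuron_types.values()}))
        for c in rows:
            a = kb.neuron_types[c.pre].subregion
            b = kb.neuron_types[c.post].subregion
            if g.has_edge(a, b):
                g[a][b]["weight"] += 1
            else:
                g.add_edge(a, b, weight=1)
    else:
        if level == "type":
            g.add_nodes_from(kb.neuron_types)
        for c in rows:
            g.add_edge(c.pre, c.post, weight=c.probability,
                       contacts=c.contacts, is_default=c.is_default)
    return g


# ---------------------------------------------------------------------------
# parcels.csv dialect
# ---------------------------------------------------------------------------

_PARCEL_COLUMNS = ["parcel_id", "volume_um3", "axonal_length_um",
                   "dendritic_length_um", "interbouton_um", "radius_um"]


def load_parcels(path: str | Path) -> list[ParcelGeometry]:
    """Read a parcels.csv file (see module docstring for the geometry)."""
    df = pd.read_csv(path)
    missing = [c for c in _PARCEL_COLUMNS if c not in df.columns]
    if missing:
        raise TableError(f"missing column(s) {missing}", str(path))
    out = []
    for i, rec in df.iterrows():
        try:
            out.append(ParcelGeometry(
                parcel_id=str(rec["parcel_id"]),
                volume=float(rec["volume_um3"]),
                axonal_length=float(rec["axonal_length_um"]),
                dendritic_length=float(rec["dendritic_length_um"]),
                interbouton_distance=float(rec["interbouton_um"]),
                interaction_radius=float(rec["radius_um"])))
        except TableError as e:
            raise TableError(str(e), str(path), int(i) + 2) from None
    return out


def write_parcels(parcels: Iterable[ParcelGeometry], path: str | Path) -> Path:
    df = pd.DataFrame(
        [(g.parcel_id, g.volume, g.axonal_length, g.dendritic_length,
          g.interbouton_distance, g.interaction_radius) for g in parcels],
        columns=_PARCEL_COLUMNS)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
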