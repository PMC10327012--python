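"""Parameter-table data model for hippocampal circuit simulations.

A :class:`KnowledgeBase` bundles the five tables needed to instantiate a
biologically detailed spiking network of the hippocampal formation:

* neuron types (subregion, excitatory/inhibitory polarity, importance rank,
  laminar code of axonal/dendritic presence per layer),
* a per-type census (neurons per hemisphere for one species),
* per-type single-compartment Izhikevich model constants,
* per-directed-pair connection probabilities and contacts per connected pair,
* per-directed-pair Tsodyks–Pawelzik–Markram (TPM) synapse constants.

Tables travel as five plain UTF-8 CSV files (one header row, "." decimal):

* ``neuron_types.csv``: ``name,subregion,polarity,rank,laminar_code``
* ``census.csv``: ``name,species,count``
* ``izhikevich.csv``: ``name,C_pF,k_nS_per_mV,Vr_mV,Vt_mV,Vpeak_mV,Vmin_mV,
  a_per_ms,b_nS,d_pA,is_default``
* ``connections.csv``: ``pre,post,probability,contacts,is_default``
* ``synapses.csv``: ``pre,post,g_nS,tau_d_ms,tau_r_ms,tau_f_ms,U,is_default``

Values filled in for missing data (class-averaged connection probabilities,
package-default neuron/synapse constants) are flagged ``is_default=true`` in
memory and in the exported files, so provenance is never silently lost.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("hippoloom")

SUBREGIONS = ("DG", "CA3", "CA2", "CA1", "Sub", "EC")
POLARITIES = ("excitatory", "inhibitory")
SPECIES = ("rat", "mouse")
RANKS = (1, 2, 3, 4, 5)

#: Class-averaged connection probabilities used to fill missing pairs,
#: keyed by connection class (pre polarity, post polarity).
DEFAULT_CLASS_PROBABILITY = {
    "EE": 0.0117,
    "EI": 0.0237,
    "IE": 0.00684,
    "II": 0.00423,
}

#: Contacts per connected pair assigned to default-filled connection rows.
DEFAULT_CONTACTS = 1.0


class TableError(ValueError):
    """A parameter-table validation failure, reported with file and row."""

    def __init__(self, message: str, table: str = "?", row: int | None = None):
        self.table = table
        self.row = row
        where = table if row is None else f"{table}, row {row}"
        super().__init__(f"[{where}] {message}")


def _check(cond: bool, message: str, table: str = "?", row: int | None = None) -> None:
    if not cond:
        raise TableError(message, table, row)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeuronType:
    """A morphologically defined neuron type.

    ``laminar_code`` is a per-layer digit string (0 = no axons or dendrites,
    1 = only axons, 2 = only dendrites, 3 = both), optionally suffixed "p"
    for cross-subregion projection.  ``rank`` grades importance for
    simplified circuit models from 1 (essential) to 5 (dispensable).
    """

    name: str
    subregion: str
    polarity: str
    rank: int
    laminar_code: str
    rank_is_default: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        _check(bool(self.name), "empty neuron type name")
        _check(self.subregion in SUBREGIONS,
               f"unknown subregion {self.subregion!r}")
        _check(self.polarity in POLARITIES,
               f"unknown polarity {self.polarity!r}")
        _check(self.rank in RANKS, f"rank {self.rank} outside 1-5")
        body = self.laminar_code[:-1] if self.laminar_code.endswith("p") \
            else self.laminar_code
        _check(len(body) > 0 and all(c in "0123" for c in body),
               f"invalid laminar code {self.laminar_code!r}")


@dataclass(frozen=True)
class CensusEntry:
    """Estimated neuron count for one type in one hemisphere of one species."""

    type_name: str
    species: str
    count: int

    def __post_init__(self) -> None:
        _check(self.species in SPECIES, f"unknown species {self.species!r}")
        _check(self.count >= 1, f"census count {self.count} must be >= 1")


@dataclass(frozen=True)
class IzhikevichParams:
    """Nine constants of the single-compartment Izhikevich hybrid model.

    Units: C pF, k nS/mV, voltages mV, a 1/ms, b nS, d pA.
    """

    C: float
    k: float
    Vr: float
    Vt: float
    Vpeak: float
    Vmin: float
    a: float
    b: float
    d: float
    is_default: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        _check(self.C > 0, "capacitance C must be positive")
        _check(self.k > 0, "scaling k must be positive")
        _check(self.a > 0, "recovery rate a must be positive")
        _check(self.Vr < self.Vt < self.Vpeak,
               f"need Vr < Vt < Vpeak, got {self.Vr}, {self.Vt}, {self.Vpeak}")
        _check(self.Vmin < self.Vpeak,
               f"post-spike reset {self.Vmin} must be below Vpeak {self.Vpeak}")


@dataclass(frozen=True)
class TPMParams:
    """Five constants of the TPM short-term plasticity synapse model.

    g: peak unitary conductance (nS); tau_d: decay; tau_r: recovery;
    tau_f: facilitation (all ms); U: utilization ratio in (0, 1].
    """

    g: float
    tau_d: float
    tau_r: float
    tau_f: float
    U: float
    is_default: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        _check(self.g > 0, "conductance g must be positive")
        for nm in ("tau_d", "tau_r", "tau_f"):
            _check(getattr(self, nm) > 0, f"{nm} must be positive")
        _check(0 < self.U <= 1, f"utilization U={self.U} outside (0, 1]")


@dataclass(frozen=True)
class ConnectionEntry:
    """Directed connection probability and contacts per connected pair."""

    pre: str
    post: str
    probability: float
    contacts: float
    is_default: bool = False

    def __post_init__(self) -> None:
        _check(0.0 <= self.probability <= 1.0,
               f"probability {self.probability} outside [0, 1]")
        if self.probability > 0:
            _check(self.contacts >= 1.0,
                   f"contacts {self.contacts} must be >= 1 when probability > 0")


#: Package defaults used when an Izhikevich or TPM row is missing.  These are
#: generic regular-spiking / depressing-synapse constants documented in
#: docs/methods.md; they carry is_default=True wherever they are filled in.
DEFAULT_IZHIKEVICH = IzhikevichParams(
    C=100.0, k=0.7, Vr=-60.0, Vt=-40.0, Vpeak=35.0, Vmin=-50.0,
    a=0.03, b=-2.0, d=100.0, is_default=True)
DEFAULT_TPM = TPMParams(
    g=1.0, tau_d=5.0, tau_r=400.0, tau_f=20.0, U=0.5, is_default=True)


@dataclass
class KnowledgeBase:
    """Cross-indexed parameter tables for one species.

    Invariants enforced by :meth:`validate`: every type referenced anywhere
    exists in ``neuron_types``; connection/synapse pairs are unique; all
    census rows carry the same species.
    """

    neuron_types: dict[str, NeuronType] = field(default_factory=dict)
    census: dict[str, CensusEntry] = field(default_factory=dict)
    izhikevich: dict[str, IzhikevichParams] = field(default_factory=dict)
    connections: dict[tuple[str, str], ConnectionEntry] = field(default_factory=dict)
    synapses: dict[tuple[str, str], TPMParams] = field(default_factory=dict)

    # -- validation --------------------------------------------------------
    def validate(self) -> "KnowledgeBase":
        names = set(self.neuron_types)
        for nm, entry in self.census.items():
            _check(nm in names, f"census references unknown type {nm!r}", "census.csv")
            _check(entry.type_name == nm, "census key/type_name mismatch", "census.csv")
        species = {e.species for e in self.census.values()}
        _check(len(species) <= 1,
               f"mixed species in one knowledge base: {sorted(species)}", "census.csv")
        for nm in self.izhikevich:
            _check(nm in names,
                   f"izhikevich references unknown type {nm!r}", "izhikevich.csv")
        for (pre, post) in self.connections:
            _check(pre in names and post in names,
                   f"connection references unknown type {pre!r}->{post!r}",
                   "connections.csv")
        for (pre, post) in self.synapses:
            _check(pre in names and post in names,
                   f"synapse references unknown type {pre!r}->{post!r}",
                   "synapses.csv")
        return self

    @property
    def species(self) -> str | None:
        for entry in self.census.values():
            return entry.species
        return None

    def polarity(self, name: str) -> str:
        return self.neuron_types[name].polarity


# ---------------------------------------------------------------------------
# Connection classes and default fill-in
# ---------------------------------------------------------------------------

def connection_class(pre_polarity: str, post_polarity: str) -> str:
    """Map a (pre, post) polarity pair to its class: EE, EI, IE or II."""
    _check(pre_polarity in POLARITIES, f"unknown polarity {pre_polarity!r}")
    _check(post_polarity in POLARITIES, f"unknown polarity {post_polarity!r}")
    code = {"excitatory": "E", "inhibitory": "I"}
    return code[pre_polarity] + code[post_polarity]


def fill_missing_probabilities(kb: KnowledgeBase) -> KnowledgeBase:
    """Complete the connection table over all ordered type pairs.

    Missing pairs (self-pairs included: recurrent populations are real)
    receive the class-averaged probability for their connection class and
    ``contacts = 1.0``, flagged ``is_default=True``.  Measured rows are kept
    untouched.  Idempotent.
    """
    kb.validate()
    out = dict(kb.connections)
    for pre in kb.neuron_types:
        for post in kb.neuron_types:
            if (pre, post) in out:
                continue
            cls = connection_class(kb.polarity(pre), kb.polarity(post))
            out[(pre, post)] = ConnectionEntry(
                pre=pre, post=post,
                probability=DEFAULT_CLASS_PROBABILITY[cls],
                contacts=DEFAULT_CONTACTS, is_default=True)
    return replace_tables(kb, connections=out)


def fill_missing_synapses(kb: KnowledgeBase) -> KnowledgeBase:
    """Give every connection row a TPM parameter set (package defaults)."""
    out = dict(kb.synapses)
    for pair in kb.connections:
        out.setdefault(pair, DEFAULT_TPM)
    return replace_tables(kb, synapses=out)


def fill_missing_izhikevich(kb: KnowledgeBase) -> KnowledgeBase:
    """Give every neuron type an Izhikevich parameter set (package defaults)."""
    out = dict(kb.izhikevich)
    for nm in kb.neuron_types:
        out.setdefault(nm, DEFAULT_IZHIKEVICH)
    return replace_tables(kb, izhikevich=out)


def fill_defaults(kb: KnowledgeBase) -> KnowledgeBase:
    """Apply all three default fill-in passes (probabilities, TPM, Izhikevich)."""
    return fill_missing_synapses(fill_missing_izhikevich(
        fill_missing_probabilities(kb)))


def replace_tables(kb: KnowledgeBase, **tables) -> KnowledgeBase:
    new = KnowledgeBase(
        neuron_types=dict(kb.neuron_types),
        census=dict(kb.census),
        izhikevich=dict(kb.izhikevich),
        connections=dict(kb.connections),
        synapses=dict(kb.synapses),
    )
    for nm, tab in tables.items():
        setattr(new, nm, tab)
    return new.validate()


# ---------------------------------------------------------------------------
# Subsetting
# ---------------------------------------------------------------------------

def select_types(kb: KnowledgeBase,
                 subregions: Iterable[str] | None = None,
                 max_rank: int = 5,
                 names: Iterable[str] | None = None) -> KnowledgeBase:
    """Restrict a knowledge base to types passing all three filters.

    ``subregions``/``names`` of None mean "no constraint".  Connection and
    synapse rows are kept only when both endpoints survive.  Unknown names
    raise :class:`TableError`.
    """
    _check(max_rank in RANKS, f"max_rank {max_rank} outside 1-5")
    sub = set(subregions) if subregions is not None else None
    if sub is not None:
        unknown = sub - set(SUBREGIONS)
        _check(not unknown, f"unknown subregions {sorted(unknown)}")
    wanted = set(names) if names is not None else None
    if wanted is not None:
        unknown = wanted - set(kb.neuron_types)
        _check(not unknown, f"unknown type names {sorted(unknown)}")

    keep = {
        nm for nm, nt in kb.neuron_types.items()
        if (sub is None or nt.subregion in sub)
        and nt.rank <= max_rank
        and (wanted is None or nm in wanted)
    }
    return KnowledgeBase(
        neuron_types={nm: t for nm, t in kb.neuron_types.items() if nm in keep},
        census={nm: c for nm, c in kb.census.items() if nm in keep},
        izhikevich={nm: p for nm, p in kb.izhikevich.items() if nm in keep},
        connections={pr: c for pr, c in kb.connections.items()
                     if pr[0] in keep and pr[1] in keep},
        synapses={pr: s for pr, s in kb.synapses.items()
                  if pr[0] in keep and pr[1] in keep},
    ).validate()


# ---------------------------------------------------------------------------
# File dialect: load / export
# ---------------------------------------------------------------------------

_FILES = ("neuron_types.csv", "census.csv", "izhikevich.csv",
          "connections.csv", "synapses.csv")

_COLUMNS = {
    "neuron_types.csv": ["name", "subregion", "polarity", "rank", "laminar_code"],
    "census.csv": ["name", "species", "count"],
    "izhikevich.csv": ["name", "C_pF", "k_nS_per_mV", "Vr_mV", "Vt_mV",
                       "Vpeak_mV", "Vmin_mV", "a_per_ms", "b_nS", "d_pA",
                       "is_default"],
    "connections.csv": ["pre", "post", "probability", "contacts", "is_default"],
    "synapses.csv": ["pre", "post", "g_nS", "tau_d_ms", "tau_r_ms",
                     "tau_f_ms", "U", "is_default"],
}


def _read_table(path: Path, table: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS[table] if c not in df.columns]
    _check(not missing, f"missing column(s) {missing}", table)
    return df


def _bool(text: str, table: str, row: int) -> bool:
    t = text.strip().lower()
    if t in ("true", "1", "yes"):
        return True
    if t in ("false", "0", "no", ""):
        return False
    raise TableError(f"cannot parse boolean {text!r}", table, row)


def _float(text: str, col: str, table: str, row: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise TableError(f"cannot parse {col}={text!r} as number", table, row)


def load_knowledge_base(source: str | Path | Mapping[str, str | Path]) -> KnowledgeBase:
    """Load and validate a knowledge base from the five-file CSV dialect.

    ``source`` is a directory containing the standard file names, or a
    mapping from file name to path.  Only ``neuron_types.csv`` is required;
    absent tables load empty.  Every violation is reported with file and row.
    """
    if isinstance(source, (str, Path)):
        base = Path(source)
        paths = {f: base / f for f in _FILES}
    else:
        paths = {f: Path(p) for f, p in source.items()}

    _check("neuron_types.csv" in paths and paths["neuron_types.csv"].exists(),
           "neuron_types.csv not found", "neuron_types.csv")

    kb = KnowledgeBase()

    tab = "neuron_types.csv"
    for i, rec in _read_table(paths[tab], tab).iterrows():
        row = int(i) + 2  # header is row 1
        try:
            rank_text = str(rec["rank"]).strip()
            if rank_text == "":
                rank, rank_default = 3, True
            else:
                try:
                    rank = int(rank_text)
                except ValueError:
                    raise TableError(f"cannot parse rank={rank_text!r}", tab, row)
                rank_default = False
            nt = NeuronType(name=rec["name"].strip(),
                            subregion=rec["subregion"].strip(),
                            polarity=rec["polarity"].strip(),
                            rank=rank, laminar_code=rec["laminar_code"].strip(),
                            rank_is_default=rank_default)
        except TableError as e:
            raise TableError(str(e).split("] ", 1)[-1], tab, row) from None
        _check(nt.name not in kb.neuron_types,
               f"duplicate type name {nt.name!r}", tab, row)
        kb.neuron_types[nt.name] = nt

    def rows_of(tab: str):
        if tab in paths and Path(paths[tab]).exists():
            for i, rec in _read_table(paths[tab], tab).iterrows():
                yield int(i) + 2, rec

    tab = "census.csv"
    for row, rec in rows_of(tab):
        try:
            count = int(rec["count"])
        except ValueError:
            raise TableError(f"cannot parse count={rec['count']!r}", tab, row)
        try:
            entry = CensusEntry(rec["name"].strip(), rec["species"].strip(), count)
        except TableError as e:
            raise TableError(str(e).split("] ", 1)[-1], tab, row) from None
        _check(entry.type_name not in kb.census,
               f"duplicate census row for {entry.type_name!r}", tab, row)
        kb.census[entry.type_name] = entry

    tab = "izhikevich.csv"
    for row, rec in rows_of(tab):
        vals = {c: _float(rec[col], col, tab, row)
                for c, col in zip(("C", "k", "Vr", "Vt", "Vpeak", "Vmin",
                                   "a", "b", "d"), _COLUMNS[tab][1:10])}
        try:
            params = IzhikevichParams(**vals,
                                      is_default=_bool(rec["is_default"], tab, row))
        except TableError as e:
            raise TableError(str(e).split("] ", 1)[-1], tab, row) from None
        nm = rec["name"].strip()
        _check(nm not in kb.izhikevich, f"duplicate izhikevich row {nm!r}", tab, row)
        kb.izhikevich[nm] = params

    tab = "connections.csv"
    for row, rec in rows_of(tab):
        try:
            entry = ConnectionEntry(
                pre=rec["pre"].strip(), post=rec["post"].strip(),
                probability=_float(rec["probability"], "probability", tab, row),
                contacts=_float(rec["contacts"], "contacts", tab, row),
                is_default=_bool(rec["is_default"], tab, row))
        except TableError as e:
            raise TableError(str(e).split("] ", 1)[-1], tab, row) from None
        pair = (entry.pre, entry.post)
        _check(pair not in kb.connections,
               f"duplicate connection row {pair}", tab, row)
        kb.connections[pair] = entry

    tab = "synapses.csv"
    for row, rec in rows_of(tab):
        vals = {c: _float(rec[col], col, tab, row)
                for c, col in zip(("g", "tau_d", "tau_r", "tau_f", "U"),
                                  _COLUMNS[tab][2:7])}
        try:
            params = TPMParams(**vals, is_default=_bool(rec["is_default"], tab, row))
        except TableError as e:
            raise TableError(str(e).split("] ", 1)[-1], tab, row) from None
        pair = (rec["pre"].strip(), rec["post"].strip())
        _check(pair not in kb.synapses, f"duplicate synapse row {pair}", tab, row)
        kb.synapses[pair] = params

    return kb.validate()


def _fmt(x: float) -> str:
    # repr round-trips floats exactly in Python 3
    return repr(float(x))


def export_knowledge_base(kb: KnowledgeBase, destination: str | Path) -> dict[str, Path]:
    """Write the five CSV files of the dialect; returns name -> path.

    Default-filled values keep their ``is_default`` flag in the dedicated
    column.  ``load_knowledge_base(export_knowledge_base(kb))`` is identity.
    """
    kb.validate()
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def write(tab: str, rows: Sequence[Sequence]) -> None:
        path = dest / tab
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(_COLUMNS[tab])
            w.writerows(rows)
        paths[tab] = path

    write("neuron_types.csv",
          [(t.name, t.subregion, t.polarity, t.rank, t.laminar_code)
           for t in kb.neuron_types.values()])
    write("census.csv",
          [(c.type_name, c.species, c.count) for c in kb.census.values()])
    write("izhikevich.csv",
          [(nm, _fmt(p.C), _fmt(p.k), _fmt(p.Vr), _fmt(p.Vt), _fmt(p.Vpeak),
            _fmt(p.Vmin), _fmt(p.a), _fmt(p.b), _fmt(p.d),
            str(p.is_default).lower())
           for nm, p in kb.izhikevich.items()])
    write("connections.csv",
          [(c.pre, c.post, _fmt(c.probability), _fmt(c.contacts),
            str(c.is_default).lower())
           for c in kb.connections.values()])
    write("synapses.csv",
          [(pre, post, _fmt(s.g), _fmt(s.tau_d), _fmt(s.tau_r), _fmt(s.tau_f),
            _fmt(s.U), str(s.is_default).lower())
           for (pre, post), s in kb.synapses.items()])
    return paths
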