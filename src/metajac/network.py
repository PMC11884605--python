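"""Metabolic network model: species, mass-action reactions, stoichiometry.

The network is the structural backbone of the whole pipeline: it supplies
the stoichiometric matrix S (species x reactions, with inflow/outflow
pseudo-reactions appended) and the structural sparsity pattern of the
biochemical Jacobian J = S * dr/dC. Only which rate depends on which
concentration matters for the pattern, so it is computed without ever
evaluating a rate law.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Species",
    "Reaction",
    "MetabolicNetwork",
    "SparsityPattern",
    "NetworkParseError",
    "NetworkValidationError",
    "load_network",
    "loads_network",
    "write_network",
    "load_builtin",
    "builtin_names",
    "stoichiometric_matrix",
    "flux_column_ids",
    "jacobian_sparsity",
]


class NetworkParseError(ValueError):
    """Raised on a malformed network file; message names the line number."""


class NetworkValidationError(ValueError):
    """Raised when a structurally complete network violates an invariant."""


@dataclass(frozen=True)
class Species:
    """A metabolite pool.

    ``pathway_tag`` groups species for pathway-level aggregation of
    differential-Jacobian scores (e.g. ``"glycosylation"`` vs
    ``"glycolysis"``).
    """

    id: str
    name: str = ""
    pathway_tag: str = ""


@dataclass(frozen=True)
class Reaction:
    """An irreversible mass-action reaction.

    The rate is ``rate_constant * prod(C_s^coeff for substrates)
    * prod(C_m for modifiers)``. Modifiers multiply the rate without being
    consumed or produced -- they model regulation between metabolites
    without substance consumption, and therefore contribute to the
    Jacobian sparsity but not to stoichiometry.
    """

    id: str
    substrates: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    modifiers: tuple[str, ...] = ()
    rate_constant: float = 1.0
    pathway_tag: str = ""


@dataclass
class MetabolicNetwork:
    """Species, reactions and boundary fluxes of a metabolic model.

    Species order is canonical: it fixes the row order of every matrix and
    table derived from the network. ``inflows`` are constant (zeroth-order)
    source fluxes, ``outflows`` first-order sinks.
    """

    species: list[Species]
    reactions: list[Reaction]
    inflows: list[tuple[str, float]] = field(default_factory=list)
    outflows: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- basic accessors -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.species)

    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    def index(self, species_id: str) -> int:
        try:
            return self.species_ids.index(species_id)
        except ValueError:
            raise KeyError(f"unknown species id {species_id!r}") from None

    def pathway_tags(self) -> dict[str, str]:
        return {s.id: s.pathway_tag for s in self.species}

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        if not self.species:
            raise NetworkValidationError("network must contain at least one species")
        ids = self.species_ids
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise NetworkValidationError(f"duplicate species ids: {dup}")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            dup = sorted({i for i in rids if rids.count(i) > 1})
            raise NetworkValidationError(f"duplicate reaction ids: {dup}")
        known = set(ids)
        for r in self.reactions:
            subs = {s for s, _ in r.substrates}
            prods = {p for p, _ in r.products}
            both = subs & prods
            if both:
                raise NetworkValidationError(
                    f"reaction {r.id!r}: species {sorted(both)} appear as both "
                    "substrate and product"
                )
            for sid, coeff in (*r.substrates, *r.products):
                if sid not in known:
                    raise NetworkValidationError(
                        f"reaction {r.id!r} references unknown species {sid!r}"
                    )
                if not (isinstance(coeff, (int, np.integer)) and coeff >= 1):
                    raise NetworkValidationError(
                        f"reaction {r.id!r}: stoichiometric coefficient for "
                        f"{sid!r} must be a positive integer, got {coeff!r}"
                    )
            for sid in r.modifiers:
                if sid not in known:
                    raise NetworkValidationError(
                        f"reaction {r.id!r} has unknown modifier {sid!r}"
                    )
            if not r.rate_constant > 0:
                raise NetworkValidationError(
                    f"reaction {r.id!r}: rate constant must be positive"
                )
        for sid, rate in self.inflows:
            if sid not in known:
                raise NetworkValidationError(f"inflow references unknown species {sid!r}")
            if not rate > 0:
                raise NetworkValidationError(f"inflow rate for {sid!r} must be positive")
        for sid, rate in self.outflows:
            if sid not in known:
                raise NetworkValidationError(f"outflow references unknown species {sid!r}")
            if not rate > 0:
                raise NetworkValidationError(f"outflow rate for {sid!r} must be positive")

    # -- perturbation ----------------------------------------------------

    def with_rate_multipliers(self, multipliers: Mapping[str, float]) -> "MetabolicNetwork":
        """Return a copy with rates scaled.

        Keys are reaction ids, ``"in:<species>"`` for inflow rates or
        ``"out:<species>"`` for outflow rate constants. Unknown keys raise
        ``KeyError`` so condition typos surface early.
        """
        rxn_ids = {r.id for r in self.reactions}
        in_ids = {f"in:{sid}" for sid, _ in self.inflows}
        out_ids = {f"out:{sid}" for sid, _ in self.outflows}
        for key in multipliers:
            if key not in rxn_ids | in_ids | out_ids:
                raise KeyError(
                    f"unknown rate id {key!r}; known ids: "
                    f"{sorted(rxn_ids | in_ids | out_ids)}"
                )
        reactions = [
            replace(r, rate_constant=r.rate_constant * multipliers.get(r.id, 1.0))
            for r in self.reactions
        ]
        inflows = [
            (sid, rate * multipliers.get(f"in:{sid}", 1.0)) for sid, rate in self.inflows
        ]
        outflows = [
            (sid, rate * multipliers.get(f"out:{sid}", 1.0)) for sid, rate in self.outflows
        ]
        return MetabolicNetwork(list(self.species), reactions, inflows, outflows)


@dataclass(frozen=True)
class SparsityPattern:
    """Index pairs (row, col) of the Jacobian allowed to be nonzero."""

    n: int
    entries: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        for i, j in self.entries:
            if not (0 <= i < self.n and 0 <= j < self.n):
                raise ValueError(f"pattern entry {(i, j)} outside [0, {self.n})")

    @property
    def n_entries(self) -> int:
        return len(self.entries)

    @property
    def identifiable(self) -> bool:
        """True when unknowns do not exceed the n(n+1)/2 covariance equations."""
        return self.n_entries <= self.n * (self.n + 1) // 2

    def sorted_entries(self) -> list[tuple[int, int]]:
        return sorted(self.entries)

    def mask(self) -> np.ndarray:
        m = np.zeros((self.n, self.n), dtype=bool)
        for i, j in self.entries:
            m[i, j] = True
        return m


# ---------------------------------------------------------------------------
# file format
# ---------------------------------------------------------------------------
#
# Tab/whitespace-separated, two sections:
#
#   #species
#   Man   mannose   glycosylation
#   #reactions
#   HK    Man       M6P   -   1.0   glycosylation
#   IN1   IN        Man   -   1.0   glycosylation
#   EF1   FBP       OUT   -   0.8   glycolysis
#
# Reaction columns: id, substrates, products, modifiers, rate_constant,
# pathway_tag; the last three are optional (modifiers default "-").
# Substrates/products use "2*A+B" syntax; reserved tokens IN/OUT mark
# boundary fluxes. Lines starting with "#" are section markers or comments.
# A file without section markers is read as a bare reaction list and its
# species are auto-collected in order of first appearance.

_SIDE_RE = re.compile(r"^(?:(\d+)\*)?([A-Za-z_][\w\-]*)$")


def _parse_side(text: str, lineno: int) -> tuple[tuple[str, int], ...]:
    out = []
    for term in text.split("+"):
        m = _SIDE_RE.match(term.strip())
        if m is None:
            raise NetworkParseError(f"line {lineno}: cannot parse species term {term!r}")
        coeff = int(m.group(1)) if m.group(1) else 1
        if coeff < 1:
            raise NetworkParseError(f"line {lineno}: non-positive coefficient in {term!r}")
        out.append((m.group(2), coeff))
    return tuple(out)


def _is_float(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def loads_network(text: str, strict: bool = False) -> MetabolicNetwork:
    """Parse a network from its TSV text (see module comment for dialect)."""
    declared: list[Species] = []
    reactions: list[Reaction] = []
    inflows: list[tuple[str, float]] = []
    outflows: list[tuple[str, float]] = []
    seen_rxn_ids: set[str] = set()
    section = "reactions"  # bare files are reaction lists
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            marker = line.lstrip("#").strip().lower()
            if marker in ("species", "reactions"):
                section = marker
            continue
        toks = line.split()
        if section == "species":
            if len(toks) < 1:
                continue
            declared.append(
                Species(
                    id=toks[0],
                    name=toks[1] if len(toks) > 1 else toks[0],
                    pathway_tag=toks[2] if len(toks) > 2 else "",
                )
            )
            continue
        # reactions section
        if len(toks) < 3:
            raise NetworkParseError(
                f"line {lineno}: reaction row needs at least id, substrates, products"
            )
        rid, subs_tok, prods_tok, *rest = toks
        if rid in seen_rxn_ids:
            raise NetworkParseError(f"line {lineno}: duplicate reaction id {rid!r}")
        seen_rxn_ids.add(rid)
        modifiers: tuple[str, ...] = ()
        rate = 1.0
        tag = ""
        if rest:
            if _is_float(rest[0]):  # short form: id subs prods rate [tag]
                rate = float(rest[0])
                rest = rest[1:]
            else:
                if rest[0] != "-":
                    modifiers = tuple(m for m in rest[0].split(",") if m)
                rest = rest[1:]
                if rest:
                    if not _is_float(rest[0]):
                        raise NetworkParseError(
                            f"line {lineno}: expected rate constant, got {rest[0]!r}"
                        )
                    rate = float(rest[0])
                    rest = rest[1:]
            if rest:
                tag = rest[0]
        if not rate > 0:
            raise NetworkParseError(f"line {lineno}: non-positive rate constant {rate}")
        if subs_tok == "IN":
            prods = _parse_side(prods_tok, lineno)
            if len(prods) != 1 or prods[0][1] != 1:
                raise NetworkParseError(f"line {lineno}: inflow must target one species")
            inflows.append((prods[0][0], rate))
            continue
        if prods_tok == "OUT":
            subs = _parse_side(subs_tok, lineno)
            if len(subs) != 1 or subs[0][1] != 1:
                raise NetworkParseError(f"line {lineno}: outflow must drain one species")
            outflows.append((subs[0][0], rate))
            continue
        reactions.append(
            Reaction(
                id=rid,
                substrates=_parse_side(subs_tok, lineno),
                products=_parse_side(prods_tok, lineno),
                modifiers=modifiers,
                rate_constant=rate,
                pathway_tag=tag,
            )
        )

    declared_ids = [s.id for s in declared]
    referenced: list[str] = []
    for r in reactions:
        for sid, _ in (*r.substrates, *r.products):
            if sid not in referenced:
                referenced.append(sid)
        for sid in r.modifiers:
            if sid not in referenced:
                referenced.append(sid)
    for sid, _ in (*inflows, *outflows):
        if sid not in referenced:
            referenced.append(sid)

    if strict:
        missing = [sid for sid in referenced if sid not in declared_ids]
        if missing:
            raise NetworkParseError(
                f"strict mode: species {missing} referenced but not declared "
                "in the #species section"
            )
    species = list(declared)
    for sid in referenced:
        if sid not in declared_ids:
            species.append(Species(id=sid, name=sid))
            declared_ids.append(sid)
    try:
        return MetabolicNetwork(species, reactions, inflows, outflows)
    except NetworkValidationError as exc:
        raise NetworkParseError(str(exc)) from exc


def load_network(path: str | Path, strict: bool = False) -> MetabolicNetwork:
    """Read a network TSV file; see :func:`loads_network` for the dialect."""
    path = Path(path)
    return loads_network(path.read_text(), strict=strict)


def _format_side(side: Iterable[tuple[str, int]]) -> str:
    return "+".join(sid if c == 1 else f"{c}*{sid}" for sid, c in side)


def write_network(net: MetabolicNetwork, path: str | Path) -> None:
    """Write the canonical TSV form; round-trips through ``load_network``."""
    lines = ["#species"]
    for s in net.species:
        lines.append(f"{s.id}\t{s.name or s.id}\t{s.pathway_tag or '-'}")
    lines.append("#reactions")
    for r in net.reactions:
        mods = ",".join(r.modifiers) if r.modifiers else "-"
        lines.append(
            f"{r.id}\t{_format_side(r.substrates)}\t{_format_side(r.products)}"
            f"\t{mods}\t{r.rate_constant!r}\t{r.pathway_tag or '-'}"
        )
    for k, (sid, rate) in enumerate(net.inflows, 1):
        lines.append(f"IN{k}\tIN\t{sid}\t-\t{rate!r}\t-")
    for k, (sid, rate) in enumerate(net.outflows, 1):
        lines.append(f"OUT{k}\t{sid}\tOUT\t-\t{rate!r}\t-")
    Path(path).write_text("\n".join(lines) + "\n")


def builtin_names() -> list[str]:
    files = resources.files("metajac") / "networks"
    return sorted(p.name[: -len(".tsv")] for p in files.iterdir() if p.name.endswith(".tsv"))


def load_builtin(name: str) -> MetabolicNetwork:
    """Load a packaged network fixture by name (e.g. ``"mannose_core"``)."""
    ref = resources.files("metajac") / "networks" / f"{name}.tsv"
    if not ref.is_file():
        raise KeyError(f"no builtin network {name!r}; available: {builtin_names()}")
    return loads_network(ref.read_text())


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------


def flux_column_ids(net: MetabolicNetwork) -> list[str]:
    """Column labels of the full stoichiometric matrix: reactions, then
    inflow/outflow pseudo-reactions."""
    return (
        [r.id for r in net.reactions]
        + [f"in:{sid}" for sid, _ in net.inflows]
        + [f"out:{sid}" for sid, _ in net.outflows]
    )


def stoichiometric_matrix(net: MetabolicNetwork) -> np.ndarray:
    """Net stoichiometry S, species x fluxes.

    S[i, k] = (product coefficient - substrate coefficient) of species i in
    flux k; inflow columns are +1 at the target species, outflow columns -1.
    """
    idx = {sid: i for i, sid in enumerate(net.species_ids)}
    m = len(net.reactions) + len(net.inflows) + len(net.outflows)
    S = np.zeros((net.n, m))
    for k, r in enumerate(net.reactions):
        for sid, c in r.substrates:
            S[idx[sid], k] -= c
        for sid, c in r.products:
            S[idx[sid], k] += c
    off = len(net.reactions)
    for k, (sid, _) in enumerate(net.inflows):
        S[idx[sid], off + k] = 1.0
    off += len(net.inflows)
    for k, (sid, _) in enumerate(net.outflows):
        S[idx[sid], off + k] = -1.0
    return S


def jacobian_sparsity(net: MetabolicNetwork) -> SparsityPattern:
    """Structural pattern of J = S * dr/dC under mass action.

    J[i, j] may be nonzero iff some reaction with net stoichiometry on
    species i has species j among its substrates or modifiers, or i == j
    and i carries an outflow. Rate constants are ignored: the pattern is
    purely structural.
    """
    idx = {sid: i for i, sid in enumerate(net.species_ids)}
    entries: set[tuple[int, int]] = set()
    for r in net.reactions:
        rows = {idx[sid] for sid, _ in (*r.substrates, *r.products)}
        net_stoich: dict[int, int] = {}
        for sid, c in r.substrates:
            net_stoich[idx[sid]] = net_stoich.get(idx[sid], 0) - c
        for sid, c in r.products:
            net_stoich[idx[sid]] = net_stoich.get(idx[sid], 0) + c
        rows = {i for i, v in net_stoich.items() if v != 0}
        cols = {idx[sid] for sid, _ in r.substrates} | {idx[m] for m in r.modifiers}
        entries.update((i, j) for i in rows for j in cols)
    for sid, _ in net.outflows:
        entries.add((idx[sid], idx[sid]))
    return SparsityPattern(n=net.n, entries=frozenset(entries))
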