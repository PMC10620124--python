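"""Parsing and ontology for Lipotype-style lipid shorthand names.

A species name is a class token (``PC``, ``Cer``, ``TAG`` ...), an optional
``O-`` ether marker, then one or more acyl/sphingoid chain tokens written
``C:D`` with an optional hydroxylation suffix ``;H``, joined by ``/``::

    PC 17:0/17:0        Cer 18:1;2/17:0       CL 16:1/15:0/15:0/15:0

Both the spaced typesetting dialect (``17 : 0``) and the compact one
(``17:0``) are accepted; canonical output is compact.  Each class maps to a
fixed chain arity and to one of five lipid categories (sterols,
sphingolipids, glycerolipids, glycerophospholipids, glycerophospholipid
intermediates).  The class -> (category, arity, ether) table ships as an
editable TSV resource (``data/class_categories.tsv``).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

from .errors import ArityError, NomenclatureError, UnknownClassError

__all__ = [
    "LipidSpecies",
    "Chain",
    "CATEGORIES",
    "CLASS_TABLE",
    "parse_species",
    "category_of",
    "arity_of",
    "canonical_name",
]

CATEGORIES = (
    "sterols",
    "sphingolipids",
    "glycerolipids",
    "glycerophospholipids",
    "glycerophospholipid intermediates",
)


def _load_class_table() -> dict[str, tuple[str, int, bool]]:
    ref = resources.files(__package__).joinpath("data/class_categories.tsv")
    table: dict[str, tuple[str, int, bool]] = {}
    with ref.open("r", encoding="utf-8") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            table[row["lipid_class"]] = (
                row["category"],
                int(row["n_chains"]),
                bool(int(row["ether"])),
            )
    return table


#: class -> (category, chain arity, is ether class)
CLASS_TABLE: dict[str, tuple[str, int, bool]] = _load_class_table()

# Longest token first so "PC O-" wins over "PC" and "LPC" over nothing.
_CLASS_TOKENS = sorted(CLASS_TABLE, key=len, reverse=True)

_CHAIN_RE = re.compile(
    r"^\s*(\d+)\s*:\s*(\d+)\s*(?:;\s*(\d+)\s*)?$"
)


@dataclass(frozen=True)
class Chain:
    """One acyl or sphingoid chain: carbons, double bonds, hydroxylations."""

    carbons: int
    double_bonds: int
    hydroxylations: int = 0

    def __post_init__(self) -> None:
        if self.carbons < 1:
            raise NomenclatureError(f"chain must have >= 1 carbon, got {self.carbons}")
        if self.double_bonds < 0 or self.hydroxylations < 0:
            raise NomenclatureError("double bonds and hydroxylations must be >= 0")


@dataclass(frozen=True)
class LipidSpecies:
    """A parsed species-level lipid with class, category and chain makeup.

    ``raw_name`` keeps the input spelling for provenance but is excluded
    from equality so that parse -> render -> parse round-trips compare equal.
    """

    raw_name: str = field(compare=False)
    lipid_class: str
    category: str
    chains: tuple[Chain, ...]
    ether: bool = False

    @property
    def total_carbons(self) -> int:
        return sum(c.carbons for c in self.chains)

    @property
    def total_double_bonds(self) -> int:
        return sum(c.double_bonds for c in self.chains)

    def __str__(self) -> str:
        return canonical_name(self)


def category_of(lipid_class: str) -> str:
    """Lipid category of a class; total over the 23-class ontology."""
    try:
        return CLASS_TABLE[lipid_class][0]
    except KeyError:
        raise UnknownClassError(f"unknown lipid class {lipid_class!r}") from None


def arity_of(lipid_class: str) -> int:
    """Number of chains a species of this class must carry."""
    try:
        return CLASS_TABLE[lipid_class][1]
    except KeyError:
        raise UnknownClassError(f"unknown lipid class {lipid_class!r}") from None


def _split_class_token(name: str) -> tuple[str, str]:
    """Split a name into (class token, chain part); raises on unknown class."""
    stripped = name.strip()
    for token in _CLASS_TOKENS:
        if stripped == token or stripped.startswith(token + " "):
            return token, stripped[len(token):].strip()
    # Report the leading word(s) up to the first digit as the offending token.
    match = re.match(r"^([^\d]*?)(?=\s*\d|$)", stripped)
    offending = (match.group(1).strip() if match else stripped) or stripped
    raise UnknownClassError(f"unknown lipid class token {offending!r} in {name!r}")


def parse_species(name: str) -> LipidSpecies:
    """Parse a shorthand species name into a :class:`LipidSpecies`.

    Whitespace-tolerant and lossless: ``parse_species(canonical_name(s))``
    equals ``s`` for every valid species.

    Raises
    ------
    UnknownClassError
        If the class token is not in the ontology.
    ArityError
        If the chain count does not match the class.
    NomenclatureError
        If a chain token is malformed.
    """
    if not isinstance(name, str) or not name.strip():
        raise NomenclatureError(f"empty or non-text lipid name: {name!r}")
    lipid_class, chain_part = _split_class_token(name)
    if not chain_part:
        raise NomenclatureError(f"no chains in lipid name {name!r}")
    chains = []
    for token in chain_part.split("/"):
        match = _CHAIN_RE.match(token)
        if match is None:
            raise NomenclatureError(
                f"malformed chain token {token.strip()!r} in {name!r}"
            )
        carbons, dbonds, hydroxy = match.groups()
        chains.append(Chain(int(carbons), int(dbonds), int(hydroxy or 0)))
    expected = arity_of(lipid_class)
    if len(chains) != expected:
        raise ArityError(
            f"{lipid_class} species must have {expected} chain(s), "
            f"got {len(chains)} in {name!r}"
        )
    category, _, ether = CLASS_TABLE[lipid_class]
    return LipidSpecies(
        raw_name=name,
        lipid_class=lipid_class,
        category=category,
        chains=tuple(chains),
        ether=ether,
    )


def canonical_name(species: LipidSpecies) -> str:
    """Deterministic compact rendering, e.g. ``Cer 18:1;2/17:0``."""
    chain_txt = "/".join(
        f"{c.carbons}:{c.double_bonds}" + (f";{c.hydroxylations}" if c.hydroxylations else "")
        for c in species.chains
    )
    return f"{species.lipid_class} {chain_txt}"


def parse_many(names: Iterable[str]) -> list[LipidSpecies]:
    """Parse an iterable of names, reporting the failing row index."""
    out = []
    for i, name in enumerate(names):
        try:
            out.append(parse_species(name))
        except NomenclatureError as exc:
            raise type(exc)(f"row {i}: {exc}") from None
    return out
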