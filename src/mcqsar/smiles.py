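"""SMILES tokenization and SMILES-side structural attributes.

The descriptor treats a SMILES string as a sequence of symbols: every atom
symbol, branch parenthesis, ring-closure digit and bond mark is one token
(``Cl``, ``Br`` and ``Si`` are single tokens).  From the token stream we
derive local attributes — one key per token (Sk) and one per adjacent token
pair (SSk) — and a fixed battery of whole-molecule codes: presence flags for
bond types (BOND), for N/O/S/P (NOSP) and for halogens (HALO), their
pairwise (PAIR) and united (HARD) combinations, the number of ring-closure
pairings (Cmax) and the nitrogen and oxygen atom counts (Nmax, Omax).

The supported dialect is the organic subset as printed in the modelled
dataset: no bracket atoms, charges, isotopes or E/Z bond marks.
"""

from __future__ import annotations

from collections import Counter
from typing import NamedTuple

from .keys import (
    AttributeKey, SK, SSK, BOND, NOSP, HALO, PAIR, HARD, CMAX, NMAX, OMAX,
)


class SmilesError(ValueError):
    """Raised for strings outside the supported SMILES dialect."""


class Token(NamedTuple):
    text: str
    position: int


_TWO_CHAR = ("Cl", "Br", "Si")
_ATOMS_UPPER = set("BCNOSPFI")
_ATOMS_LOWER = set("bcnosp")
_SYMBOLS = set("()=#@") | set("123456789")


def tokenize(smiles: str) -> list[Token]:
    """Split a SMILES string into symbol tokens.

    Whitespace is stripped first (printed tables sometimes break strings
    with spaces).  Concatenating the token texts reproduces the stripped
    input exactly.
    """
    s = "".join(smiles.split())
    if not s:
        raise SmilesError("empty SMILES string")
    tokens: list[Token] = []
    i = 0
    while i < len(s):
        two = s[i:i + 2]
        if two in _TWO_CHAR:
            tokens.append(Token(two, i))
            i += 2
            continue
        ch = s[i]
        if ch in _ATOMS_UPPER or ch in _ATOMS_LOWER or ch in _SYMBOLS:
            tokens.append(Token(ch, i))
            i += 1
            continue
        raise SmilesError(f"unsupported character {ch!r} at position {i}")
    return tokens


def is_atom_token(text: str) -> bool:
    return text in _TWO_CHAR or text in _ATOMS_UPPER or text in _ATOMS_LOWER


def local_attributes(tokens: list[Token]) -> Counter[AttributeKey]:
    """Sk and SSk keys: one per token, one per adjacent token pair.

    Pairs are canonicalized by sorting the two texts, so reading the string
    backwards yields the same SSk multiset.
    """
    counts: Counter[AttributeKey] = Counter()
    for tok in tokens:
        counts[AttributeKey(SK, tok.text)] += 1
    for a, b in zip(tokens, tokens[1:]):
        lo, hi = sorted((a.text, b.text))
        counts[AttributeKey(SSK, f"{lo}.{hi}")] += 1
    return counts


def _flags(payload_items: list[tuple[str, bool]]) -> str:
    return "".join(f"{name}{int(flag)}" for name, flag in payload_items)


def ring_closure_pairings(tokens: list[Token]) -> int:
    """Number of ring-bond pairings formed by ring-closure digits.

    Digits may be reused once closed; an unmatched digit is an error.
    """
    open_digits: dict[str, int] = {}
    pairings = 0
    for tok in tokens:
        if tok.text in "123456789":
            if tok.text in open_digits:
                del open_digits[tok.text]
                pairings += 1
            else:
                open_digits[tok.text] = tok.position
    if open_digits:
        digit, pos = next(iter(open_digits.items()))
        raise SmilesError(f"unmatched ring-closure digit {digit!r} opened at position {pos}")
    return pairings


def global_attributes(tokens: list[Token], include_halo: bool = True) -> Counter[AttributeKey]:
    """Whole-molecule attribute keys, each with multiplicity one.

    Emits BOND, NOSP, HALO, three PAIR combinations, HARD, Cmax (ring-bond
    count) and the Nmax/Omax atom counts.  ``include_halo=False`` drops the
    standalone HALO key while keeping it inside PAIR and HARD.
    """
    texts = [t.text for t in tokens]
    atoms = [t for t in texts if is_atom_token(t)]
    bond = _flags([("=", "=" in texts), ("#", "#" in texts), ("@", "@" in texts)])
    upper = {a.upper() for a in atoms if len(a) == 1}
    nosp = _flags([(el, el in upper) for el in "NOSP"])
    halo = _flags([
        ("F", "F" in atoms), ("Cl", "Cl" in atoms),
        ("Br", "Br" in atoms), ("I", "I" in atoms),
    ])
    counts: Counter[AttributeKey] = Counter()
    counts[AttributeKey(BOND, bond)] = 1
    counts[AttributeKey(NOSP, nosp)] = 1
    if include_halo:
        counts[AttributeKey(HALO, halo)] = 1
    counts[AttributeKey(PAIR, f"{bond}|{nosp}")] = 1
    counts[AttributeKey(PAIR, f"{bond}|{halo}")] = 1
    counts[AttributeKey(PAIR, f"{nosp}|{halo}")] = 1
    counts[AttributeKey(HARD, f"{bond}|{nosp}|{halo}")] = 1
    counts[AttributeKey(CMAX, str(ring_closure_pairings(tokens)))] = 1
    n_count = sum(1 for a in atoms if a.upper() == "N")
    o_count = sum(1 for a in atoms if a.upper() == "O")
    counts[AttributeKey(NMAX, str(n_count))] = 1
    counts[AttributeKey(OMAX, str(o_count))] = 1
    return counts


def smiles_attributes(smiles: str, include_halo: bool = True) -> Counter[AttributeKey]:
    """All SMILES-side attributes of one molecule."""
    tokens = tokenize(smiles)
    counts = local_attributes(tokens)
    counts.update(global_attributes(tokens, include_halo=include_halo))
    return counts
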