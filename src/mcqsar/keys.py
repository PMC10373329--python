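"""Structural attribute keys.

Every molecular feature that can carry a correlation weight is identified by
an :class:`AttributeKey` — a ``(namespace, payload)`` pair.  The namespace
says which family of features the key belongs to (single SMILES symbol,
symbol pair, global presence code, graph invariant, ...); the payload is a
canonical string that pins down the feature within the family.  Keys
serialize as ``"NAMESPACE:payload"`` and that serialized form is stable
across runs, which makes model files diffable.
"""

from __future__ import annotations

from typing import NamedTuple

#: Namespaces for SMILES-derived attributes.
SK = "SK"          # one SMILES symbol
SSK = "SSK"        # unordered pair of adjacent SMILES symbols
BOND = "BOND"      # presence flags for =, #, @
NOSP = "NOSP"      # presence flags for N, O, S, P
HALO = "HALO"      # presence flags for F, Cl, Br, I
PAIR = "PAIR"      # pairwise combinations of BOND/NOSP/HALO
HARD = "HARD"      # BOND+NOSP+HALO united code
CMAX = "CMAX"      # ring-closure pairing count
NMAX = "NMAX"      # nitrogen atom count
OMAX = "OMAX"      # oxygen atom count

#: Namespaces for hydrogen-suppressed-graph attributes.
EC = "EC"          # Morgan extended connectivity (orders 1 and 2)
PT = "PT"          # simple-path counts (lengths 2 and 3)
SHELL = "SHELL"    # valence shells (distances 2 and 3)
COMBO = "COMBO"    # sums / absolute differences of paired invariants
RING = "RING"      # 5-/6-ring codes

NAMESPACES = frozenset({
    SK, SSK, BOND, NOSP, HALO, PAIR, HARD, CMAX, NMAX, OMAX,
    EC, PT, SHELL, COMBO, RING,
})

#: Namespaces whose keys appear at most once per molecule.
GLOBAL_NAMESPACES = frozenset({BOND, NOSP, HALO, PAIR, HARD, CMAX, NMAX, OMAX, RING})


class AttributeKey(NamedTuple):
    namespace: str
    payload: str

    def __str__(self) -> str:
        return f"{self.namespace}:{self.payload}"

    @classmethod
    def parse(cls, text: str) -> "AttributeKey":
        ns, sep, payload = text.partition(":")
        if not sep or ns not in NAMESPACES:
            raise ValueError(f"not a serialized attribute key: {text!r}")
        return cls(ns, payload)
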