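"""Independent brute-force digestion oracle used only by tests.

Deliberately coded apart from the engine: the six-position context of
each bond is materialised as a padded window string, and a pattern
matches when every constrained window character is in its residue set
(the pad character fails automatically, giving the off-terminus
semantics).
"""

from __future__ import annotations

import numpy as np

from peptimine.rules import CleavagePattern, ProteaseSpec

_PAD = "-"
_ORDER = ("P4", "P3", "P2", "P1", "P1'", "P2'")


def oracle_sites(sequence: str, spec: ProteaseSpec) -> list[int]:
    padded = _PAD * 3 + sequence + _PAD * 2
    sites = []
    for bond in range(1, len(sequence)):
        ctx = padded[bond - 1 : bond + 5]  # P4 P3 P2 P1 P1' P2'
        window = dict(zip(_ORDER, ctx))
        if any(
            all(window[pos] in residues for pos, residues in pat.constraints.items())
            for pat in spec.patterns
        ):
            sites.append(bond)
    return sites


def oracle_fragments(sequence: str, sites: list[int]) -> list[str]:
    out, prev = [], 0
    for s in sites:
        out.append(sequence[prev:s])
        prev = s
    out.append(sequence[prev:])
    return out


_AA = sorted("ACDEFGHIKLMNPQRSTVWY")


def random_spec(rng: np.random.Generator, name: str = "rand") -> ProteaseSpec:
    """A random enzyme: 1-3 patterns, each P1 plus optional context."""
    patterns = []
    for _ in range(int(rng.integers(1, 4))):
        constraints = {"P1": frozenset(rng.choice(_AA, size=int(rng.integers(1, 5)), replace=False))}
        for pos in ("P2", "P1'", "P3", "P2'"):
            if rng.random() < 0.25:
                constraints[pos] = frozenset(
                    rng.choice(_AA, size=int(rng.integers(1, 7)), replace=False)
                )
        patterns.append(CleavagePattern(constraints))
    return ProteaseSpec(name=name, ec_number="3.4.22.99", patterns=tuple(patterns))


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length))
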