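"""Nearest-neighbor free-energy parameters for RNA:RNA duplexes.

Stack free energies (ΔG°37, kcal/mol) for Watson–Crick and G·U wobble
base-pair steps, after the Turner-group nearest-neighbor compilations
(Watson–Crick set with the standard wobble extensions).  The table is
versioned configuration, not hard-coded truth: an alternative parameter
set with the same pair vocabulary can be passed to
:func:`exomir.targets.duplex_energy`.

A step is keyed ``(pair1, pair2)`` where ``pair1 = (a, b)`` is the
5′-side base pair (strand-1 base a, strand-2 base b) and ``pair2`` the
adjacent pair one step in the 3′ direction of strand 1.  Reading the
duplex from the other end maps ``(p1, p2) -> (rev(p2), rev(p1))``; the
table is symmetric under that involution (asserted at import), which
makes the computed energy invariant under simultaneous strand reversal.

Loop penalties and the duplex initiation term are coarse single-number
terms: this model scores short miRNA:target duplexes, where stack terms
dominate, not long structured RNAs.
"""

from __future__ import annotations

import math

__all__ = [
    "PAIRS",
    "STACK",
    "INITIATION",
    "bulge_penalty",
    "internal_penalty",
    "can_pair",
]

PARAMS_VERSION = "turner-wc-wobble-dg37-v1"

# allowed base pairs, RNA alphabet (A,C,G,U)
PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}

INITIATION = 4.09  # kcal/mol, intermolecular duplex initiation

# Unique measured stacks; symmetric partners are filled below.
_CORE: dict[tuple[tuple[str, str], tuple[str, str]], float] = {
    # Watson-Crick / Watson-Crick
    (("A", "U"), ("A", "U")): -0.93,
    (("A", "U"), ("U", "A")): -1.10,
    (("U", "A"), ("A", "U")): -1.33,
    (("C", "G"), ("A", "U")): -2.11,
    (("C", "G"), ("U", "A")): -2.08,
    (("G", "C"), ("A", "U")): -2.35,
    (("G", "C"), ("U", "A")): -2.24,
    (("C", "G"), ("G", "C")): -2.36,
    (("G", "C"), ("C", "G")): -3.42,
    (("G", "C"), ("G", "C")): -3.26,
    # Watson-Crick / wobble
    (("A", "U"), ("G", "U")): -0.55,
    (("A", "U"), ("U", "G")): -1.36,
    (("C", "G"), ("G", "U")): -1.41,
    (("C", "G"), ("U", "G")): -2.11,
    (("G", "C"), ("G", "U")): -1.53,
    (("G", "C"), ("U", "G")): -2.51,
    (("U", "A"), ("G", "U")): -1.00,
    (("U", "A"), ("U", "G")): -1.27,
    # wobble / wobble
    (("G", "U"), ("G", "U")): -0.50,
    (("G", "U"), ("U", "G")): +0.47,
    (("U", "G"), ("G", "U")): -0.30,
}


def _rev(pair: tuple[str, str]) -> tuple[str, str]:
    return (pair[1], pair[0])


def _build_stack() -> dict[tuple[tuple[str, str], tuple[str, str]], float]:
    stack: dict[tuple[tuple[str, str], tuple[str, str]], float] = {}
    for (p1, p2), v in _CORE.items():
        partner = (_rev(p2), _rev(p1))
        for key in ((p1, p2), partner):
            if key in stack and stack[key] != v:
                raise AssertionError(f"inconsistent symmetric stack for {key}")
            stack[key] = v
    # all 36 pair steps must be covered and symmetric
    assert len(stack) == 36, len(stack)
    for (p1, p2), v in stack.items():
        assert stack[(_rev(p2), _rev(p1))] == v
    return stack


STACK = _build_stack()


def can_pair(a: str, b: str) -> bool:
    return (a, b) in PAIRS


def bulge_penalty(n: int) -> float:
    """Free-energy penalty (kcal/mol) of a bulge of n unpaired bases."""
    table = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
    if n in table:
        return table[n]
    return table[6] + 1.08 * math.log(n / 6.0)


def internal_penalty(n: int) -> float:
    """Penalty of an internal loop with n unpaired bases in total."""
    table = {2: 1.5, 3: 2.2, 4: 2.5, 5: 3.0, 6: 3.5}
    if n in table:
        return table[n]
    return table[6] + 1.08 * math.log(n / 6.0)
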