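"""Canonical hand degrees of freedom (DoF).

Sixteen anatomical joint angles of the right hand, as recorded by an
instrumented glove against a flat-hand reference posture (all angles zero with
the hand resting flat, fingers together): flexion/extension of the
metacarpophalangeal (MCP) joints of all digits, of the proximal interphalangeal
(PIP) joints of the fingers and of the thumb interphalangeal (IP) joint;
flexion and abduction of the thumb carpometacarpal (CMC) joint; relative
abduction between adjacent finger pairs; and the palmar arch.

The ordering defined here is the canonical column order of every angle matrix
this package produces or consumes.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class DoFLabel:
    """One recorded hand degree of freedom.

    Attributes
    ----------
    name:
        Canonical label, e.g. ``"PIP4F"``.
    digit:
        Digit index 1 (thumb) .. 5 (little finger). Inter-finger abductions
        carry the lower of the two digits they span; the palmar arch carries 0.
    kind:
        ``"flexion"``, ``"abduction"`` or ``"arch"``.
    """

    name: str
    digit: int
    kind: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


DOF_LABELS: tuple[DoFLabel, ...] = (
    DoFLabel("CMC1F", 1, "flexion"),
    DoFLabel("CMC1A", 1, "abduction"),
    DoFLabel("MCP1F", 1, "flexion"),
    DoFLabel("IP1F", 1, "flexion"),
    DoFLabel("MCP2F", 2, "flexion"),
    DoFLabel("PIP2F", 2, "flexion"),
    DoFLabel("MCP3F", 3, "flexion"),
    DoFLabel("PIP3F", 3, "flexion"),
    DoFLabel("MCP4F", 4, "flexion"),
    DoFLabel("PIP4F", 4, "flexion"),
    DoFLabel("MCP5F", 5, "flexion"),
    DoFLabel("PIP5F", 5, "flexion"),
    DoFLabel("MCP2-3A", 2, "abduction"),
    DoFLabel("MCP3-4A", 3, "abduction"),
    DoFLabel("MCP4-5A", 4, "abduction"),
    DoFLabel("PalmArch", 0, "arch"),
)

DOF_NAMES: tuple[str, ...] = tuple(d.name for d in DOF_LABELS)
N_DOF: int = len(DOF_LABELS)

_INDEX: dict[str, int] = {d.name: i for i, d in enumerate(DOF_LABELS)}


def dof_index(name: str) -> int:
    """Return the canonical column index of a DoF label.

    Raises
    ------
    KeyError
        If ``name`` is not one of the 16 canonical labels.
    """
    return _INDEX[name]


def canonical_sort(names) -> list[str]:
    """Sort DoF names into canonical column order."""
    return sorted(names, key=dof_index)
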