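"""Restriction enzyme specifications.

4C-seq uses a primary six-cutter to define restriction fragments around the
bait and a secondary four-cutter to circularise the ligation products.  Only
the recognition motif and the cut offset within it matter for the in-silico
digestion; star activity, methylation sensitivity and buffer conditions are
out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme as a plain DNA motif plus cut offset.

    Parameters
    ----------
    name:
        Display name, e.g. ``"HindIII"``.
    motif:
        Recognition sequence, uppercase ACGT only (no IUPAC ambiguity codes).
        Must be palindromic: all digestion scans run on the forward strand
        only, which is complete iff the site reads the same on both strands.
    cut_offset:
        Distance in bases from the motif start to the cut position on the
        forward strand (``A^AGCTT`` has offset 1).
    """

    name: str
    motif: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.motif or any(b not in "ACGT" for b in self.motif):
            raise ValueError(
                f"{self.name}: motif must be non-empty uppercase ACGT, got {self.motif!r}"
            )
        if not 0 <= self.cut_offset <= len(self.motif):
            raise ValueError(
                f"{self.name}: cut_offset {self.cut_offset} outside motif of length {len(self.motif)}"
            )
        if reverse_complement(self.motif) != self.motif:
            raise ValueError(
                f"{self.name}: motif {self.motif} is not palindromic; forward-strand "
                "scanning would miss reverse-strand sites"
            )


# Canonical REBASE specificities for the enzymes used in liver 4C designs.
HINDIII = EnzymeSpec("HindIII", "AAGCTT", 1)  # A^AGCTT
ECORI = EnzymeSpec("EcoRI", "GAATTC", 1)      # G^AATTC
CSP6I = EnzymeSpec("Csp6I", "GTAC", 1)        # G^TAC

ENZYMES: dict[str, EnzymeSpec] = {e.name: e for e in (HINDIII, ECORI, CSP6I)}


def get_enzyme(name: str) -> EnzymeSpec:
    """Look up an enzyme by name in the built-in registry."""
    try:
        return ENZYMES[name]
    except KeyError:
        known = ", ".join(sorted(ENZYMES))
        raise KeyError(f"unknown enzyme {name!r}; registered: {known}") from None
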