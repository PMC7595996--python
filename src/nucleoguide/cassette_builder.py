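"""Cloning-ready sgRNA cassette inserts and annealed-oligo pairs.

In the Pol II-driven single-transcript scheme, the sgRNA is flanked by a
hammerhead ribozyme (5') and an HDV ribozyme (3') so that self-cleavage
releases the functional guide. The hammerhead's first six bases must be
the reverse complement of the spacer's first six bases to form its
cleavage-competent stem, so the 5' flank is guide-specific while the
catalytic core is constant. The destination plasmid carries the tracrRNA
scaffold and the HDV ribozyme; the insert contributed by the annealed
oligo pair is hammerhead + spacer, dropped into a single Eco91I (BstEII)
site directly upstream of the scaffold.

The core and HDV sequences shipped here are the public sequences of that
cassette scheme; the single-stranded overhangs depend on the destination
backbone and must be confirmed by the user.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .dna import revcomp

#: Constant hammerhead catalytic core appended after the guide-specific hexamer.
HAMMERHEAD_CORE = "CTGATGAGTCCGTGAGGACGAAACGAGTAAGCTCGTC"

#: HDV ribozyme (resident on the destination plasmid in the default split).
HDV_RIBOZYME = (
    "GGCCGGCATGGTCCCAGCCTCCTCGCTGGCGCCGGCTGGGCAACATGCTTCGGCATGGCGAATGGGAC"
)

#: Eco91I/BstEII recognition site G^GTNACC leaves a 5-nt 5' overhang.
ECO91I_OVERHANG_LENGTH = 5


class CassetteError(ValueError):
    pass


@dataclass
class OverhangSpec:
    """Single-stranded 5' extensions prepended to each oligo.

    `expected_length`, when set (e.g. 5 for Eco91I), is enforced against
    both overhangs.
    """

    forward: str = ""
    reverse: str = ""
    expected_length: int | None = None

    def __post_init__(self) -> None:
        if self.expected_length is not None:
            for name, ov in (("forward", self.forward), ("reverse", self.reverse)):
                if len(ov) != self.expected_length:
                    raise CassetteError(
                        f"{name} overhang {ov!r} incompatible with declared "
                        f"restriction scheme (need {self.expected_length} nt)")


@dataclass
class CassetteInsert:
    spacer: str
    hammerhead: str
    insert: str
    forward_oligo: str
    reverse_oligo: str
    overhangs: OverhangSpec = field(default_factory=OverhangSpec)


def _check_spacer(spacer: str) -> None:
    if set(spacer) - set("ACGT"):
        raise CassetteError(
            f"spacer {spacer!r} contains ambiguous bases; unsuitable for a "
            "hammerhead cassette")


def build_hammerhead(spacer: str, core: str = HAMMERHEAD_CORE) -> str:
    """Guide-specific hammerhead: revcomp(spacer[0:6]) + constant core."""
    _check_spacer(spacer)
    return revcomp(spacer[:6]) + core


def emit_oligos(spacer: str, overhangs: OverhangSpec | None = None,
                core: str = HAMMERHEAD_CORE) -> CassetteInsert:
    """Annealed-oligo pair reconstructing the hammerhead+spacer insert.

    The double-stranded portion of the duplex is exactly `insert`; each
    oligo carries its configured 5' single-stranded overhang. With empty
    overhangs, forward_oligo == insert and reverse_oligo == revcomp(insert).
    """
    overhangs = overhangs or OverhangSpec()
    insert = build_hammerhead(spacer, core) + spacer
    return CassetteInsert(
        spacer=spacer,
        hammerhead=build_hammerhead(spacer, core),
        insert=insert,
        forward_oligo=overhangs.forward + insert,
        reverse_oligo=overhangs.reverse + revcomp(insert),
        overhangs=overhangs,
    )


def spacer_from_insert(insert: str, core: str = HAMMERHEAD_CORE) -> str:
    """Recover the spacer from its fixed offset in the insert (round-trip)."""
    offset = 6 + len(core)
    spacer = insert[offset:offset + 20]
    if insert[:6] != revcomp(spacer[:6]) or insert[6:offset] != core:
        raise CassetteError("insert does not follow the hammerhead+spacer layout")
    return spacer
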