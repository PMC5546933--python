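"""Target loci, guides and protospacer-relative coordinates.

Coordinate convention used throughout the package: protospacer position 1 is
the 5'-most (PAM-distal) base of the guide match on the non-target strand.
For a 20-nt guide the PAM occupies positions 21-23; for truncated guides of
length L the PAM starts at L+1. Positions 5' of the protospacer are negative
1-based distances with no position 0 (..., -2, -1, 1, 2, ...), so "-38" means
38 bp upstream of the first protospacer base. Amplicon offsets are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Region labels for protospacer-relative positions.
UPSTREAM = "upstream"
WINDOW = "window"
PROTOSPACER = "protospacer"
PAM = "pam"
DOWNSTREAM = "downstream"


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N, case kept)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    """Complement of a single base (or string, without reversal)."""
    return base.translate(_COMPLEMENT)


def normalize_seq(seq: str) -> str:
    """Uppercase a nucleotide string and map RNA U to T."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class GuideRNA:
    """A guide RNA spacer, written 5'->3' in non-target-strand (protospacer) sense.

    Full-length guides are 20 nt; truncated variants of 16 or 17 nt are
    accepted (guide length only changes where the PAM-relative numbering
    ends, never where position 1 sits).
    """

    name: str
    spacer: str

    def __post_init__(self) -> None:
        spacer = normalize_seq(self.spacer)
        object.__setattr__(self, "spacer", spacer)
        if not spacer or set(spacer) - set("ACGT"):
            raise ValueError(f"guide {self.name!r}: spacer must contain only A/C/G/T")
        if not 16 <= len(spacer) <= 20:
            raise ValueError(
                f"guide {self.name!r}: spacer length {len(spacer)} outside [16, 20]"
            )

    def __len__(self) -> int:
        return len(self.spacer)

    def seed(self, seed_len: int = 10) -> str:
        """The 3'-most (PAM-proximal) ``seed_len`` bases of the spacer."""
        return self.spacer[-seed_len:]


@dataclass(frozen=True)
class RelPosition:
    """A protospacer-relative coordinate plus the region it falls in."""

    value: int
    region: str

    def __int__(self) -> int:
        return self.value


@dataclass(frozen=True)
class TargetLocus:
    """A reference amplicon with the protospacer/PAM geometry of one guide.

    Parameters
    ----------
    amplicon
        Reference amplicon sequence (the plus strand of the sequencing
        reference).
    protospacer_start
        0-based offset of the leftmost amplicon base covered by the
        protospacer, regardless of strand.
    strand
        ``"+"`` when the protospacer reads in amplicon orientation, ``"-"``
        when it lies on the reverse complement.
    window
        Inclusive protospacer-position range of the canonical deamination
        window; cytidine deaminase editing concentrates at positions 4-8.
    """

    name: str
    amplicon: str
    protospacer_start: int
    strand: str
    guide: GuideRNA
    window: tuple[int, int] = (4, 8)

    def __post_init__(self) -> None:
        amplicon = normalize_seq(self.amplicon)
        object.__setattr__(self, "amplicon", amplicon)
        object.__setattr__(self, "window", tuple(self.window))
        if self.strand not in ("+", "-"):
            raise ValueError(f"locus {self.name!r}: strand must be '+' or '-'")
        L = len(self.guide)
        s = self.protospacer_start
        if not (0 <= s and s + L <= len(amplicon)):
            raise ValueError(f"locus {self.name!r}: protospacer outside amplicon")
        observed = amplicon[s : s + L]
        if self.strand == "-":
            observed = revcomp(observed)
        if observed != self.guide.spacer:
            raise ValueError(
                f"locus {self.name!r}: amplicon does not contain the guide spacer "
                f"at offset {s} on strand {self.strand} (saw {observed})"
            )
        lo, hi = self.window
        if not (1 <= lo <= hi <= L):
            raise ValueError(f"locus {self.name!r}: window {self.window} outside [1, {L}]")
        pam = self.pam
        if len(pam) != 3 or pam[1:] != "GG":
            raise ValueError(f"locus {self.name!r}: PAM {pam!r} does not match NGG")

    # -- geometry ---------------------------------------------------------

    @property
    def pam(self) -> str:
        """The 3-nt PAM immediately 3' of the protospacer, in guide sense."""
        s, L = self.protospacer_start, len(self.guide)
        if self.strand == "+":
            return self.amplicon[s + L : s + L + 3]
        return revcomp(self.amplicon[s - 3 : s])

    def region_of(self, value: int) -> str:
        """Region label for a protospacer-relative coordinate."""
        if value == 0:
            raise ValueError("protospacer-relative coordinates have no position 0")
        L = len(self.guide)
        lo, hi = self.window
        if value < 1:
            return UPSTREAM
        if value <= L:
            return WINDOW if lo <= value <= hi else PROTOSPACER
        if value <= L + 3:
            return PAM
        return DOWNSTREAM

    def rel(self, value: int) -> RelPosition:
        """Build a :class:`RelPosition` for a relative coordinate."""
        return RelPosition(value, self.region_of(value))

    def to_relative(self, amplicon_offset: int) -> RelPosition:
        """Map a 0-based amplicon offset to a protospacer-relative position.

        Bijective with :meth:`from_relative` over the amplicon; the relative
        axis runs in guide orientation, so on minus-strand loci it counts
        rightward-to-leftward along the amplicon.
        """
        if not 0 <= amplicon_offset < len(self.amplicon):
            raise IndexError(
                f"offset {amplicon_offset} outside amplicon [0, {len(self.amplicon)})"
            )
        s, L = self.protospacer_start, len(self.guide)
        if self.strand == "+":
            raw = amplicon_offset - s
        else:
            raw = (s + L - 1) - amplicon_offset
        value = raw + 1 if raw >= 0 else raw
        return self.rel(value)

    def from_relative(self, value: int) -> int:
        """Map a protospacer-relative coordinate back to a 0-based amplicon offset."""
        if value == 0:
            raise ValueError("protospacer-relative coordinates have no position 0")
        raw = value - 1 if value > 0 else value
        s, L = self.protospacer_start, len(self.guide)
        offset = s + raw if self.strand == "+" else (s + L - 1) - raw
        if not 0 <= offset < len(self.amplicon):
            raise IndexError(f"relative position {value} maps outside the amplicon")
        return offset

    def proximal_distance(self, value: int) -> int:
        """Distance (bp) of a relative position outside the protospacer; 0 inside.

        PAM bases count as distance 1-3 past the protospacer's 3' end,
        upstream positions as their 1-based 5' distance.
        """
        if value < 0:
            return -value
        return max(0, value - len(self.guide))
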