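"""The unzipping construct: segment sequence, arms and annotated sites.

All downstream coordinates live in the construct's unzip frame: 0-based,
half-open, increasing in the direction of fork progression (which is also
the direction of motor translocation in the roadblock assays).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALID_KINDS = {"protospacer", "PAM", "A20", "promoter", "template_end"}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Annotation:
    name: str
    start: int
    end: int
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown annotation kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    @property
    def mid(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class UnzipConstruct:
    """Unzipping segment plus dsDNA arms, in the unzip coordinate frame.

    Parameters
    ----------
    sequence : str
        Segment strand read in the direction of fork progression.
    arm_bp : int
        Total dsDNA arm contour, bp (both arms combined).
    direction : str
        'PAM-distal-first' if the fork (and motor) meets the PAM-distal
        side of the Cas complex first, else 'PAM-proximal-first'.
    annotations : list of Annotation
        Site annotations in the unzip frame, 0-based half-open.
    """

    sequence: str
    arm_bp: int
    direction: str
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if set(self.sequence) - set("ACGT"):
            bad = sorted(set(self.sequence) - set("ACGT"))
            raise ValueError(f"non-ACGT characters in sequence: {bad}")
        if self.direction not in ("PAM-distal-first", "PAM-proximal-first"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.arm_bp <= 0:
            raise ValueError("arm_bp must be positive")
        L = len(self.sequence)
        for a in self.annotations:
            if a.end > L:
                raise ValueError(
                    f"annotation {a.name} [{a.start},{a.end}) outside segment of {L} bp"
                )
        proto = self._find("protospacer")
        pam = self._find("PAM")
        if proto and pam:
            adjacent = pam.start == proto.end or pam.end == proto.start
            if not adjacent:
                raise ValueError("PAM must be adjacent to the protospacer")
            if self.direction == "PAM-distal-first" and pam.start != proto.end:
                raise ValueError(
                    "PAM-distal-first requires the PAM after the protospacer "
                    "in the unzip coordinate"
                )
            if self.direction == "PAM-proximal-first" and pam.end != proto.start:
                raise ValueError(
                    "PAM-proximal-first requires the PAM before the protospacer"
                )

    def _find(self, kind: str) -> Annotation | None:
        hits = [a for a in self.annotations if a.kind == kind]
        return hits[0] if hits else None

    def require(self, kind: str) -> Annotation:
        a = self._find(kind)
        if a is None:
            raise ValueError(f"construct has no {kind} annotation")
        return a

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def protospacer(self) -> Annotation:
        return self.require("protospacer")

    @property
    def pam(self) -> Annotation:
        return self.require("PAM")

    @property
    def a20_position(self) -> float:
        return self.require("A20").mid

    @property
    def dcas_site(self) -> int:
        """PAM-proximal edge of the protospacer — the anchor of the
        collision-competence distance rule."""
        proto, pam = self.protospacer, self.pam
        return proto.end if pam.start == proto.end else proto.start

    @property
    def rloop_window(self) -> tuple[int, int]:
        """gRNA-DNA hybrid interval (the DNA-bubble region) in the unzip frame."""
        p = self.protospacer
        return (p.start, p.end)

    @property
    def rloop_upstream_edge(self) -> int:
        """Hybrid edge nearer the approaching motor (smaller unzip coordinate)."""
        return self.rloop_window[0]

    def flipped(self) -> "UnzipConstruct":
        """The same physical molecule unzipped from the opposite end."""
        L = self.length
        new_dir = (
            "PAM-proximal-first"
            if self.direction == "PAM-distal-first"
            else "PAM-distal-first"
        )
        anns = [
            Annotation(a.name, L - a.end, L - a.start, a.kind)
            for a in self.annotations
        ]
        return UnzipConstruct(
            reverse_complement(self.sequence), self.arm_bp, new_dir, anns
        )


def demo_construct(
    length: int = 560,
    arm_bp: int = 800,
    a20: int = 120,
    protospacer_start: int = 429,
    protospacer_len: int = 20,
    gc_fraction: float = 0.5,
    seed: int = 20220864,
) -> UnzipConstruct:
    """A synthetic PAM-distal-first roadblock template.

    Emulates the assay geometry: a promoter with the stall site (A20) early
    in the segment and a Cas target ~309 bp downstream, PAM on the far side
    of the protospacer from the approaching motor.  The sequence itself is
    random at the requested GC content (fixed default seed so the demo
    construct is stable across runs).
    """
    rng = np.random.default_rng(seed)
    p_at = (1 - gc_fraction) / 2
    p_gc = gc_fraction / 2
    seq = "".join(
        rng.choice(list("ACGT"), size=length, p=[p_at, p_gc, p_gc, p_at])
    )
    ps, pe = protospacer_start, protospacer_start + protospacer_len
    anns = [
        Annotation("promoter", a20 - 40, a20 - 20, "promoter"),
        Annotation("A20", a20, a20 + 1, "A20"),
        Annotation("target", ps, pe, "protospacer"),
        Annotation("PAM", pe, pe + 3, "PAM"),
        Annotation("end", length - 1, length, "template_end"),
    ]
    return UnzipConstruct(seq, arm_bp, "PAM-distal-first", anns)
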