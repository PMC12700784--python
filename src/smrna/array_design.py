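"""Tiled crRNA CRISPR-array design and overlap-extension build planning.

Designs type III CRISPR arrays that label an mRNA with many crRNAs at once:

1. **Tiling** — consecutive, non-overlapping 36-nt windows along the 3′ UTR
   of the target transcript (the UTR is chosen so the crRNAs do not interfere
   with translation); each spacer is the exact reverse complement of its
   window, so the crRNA base-pairs with the mRNA.
2. **Splitting** — the spacer set is divided contiguously and near-evenly
   across a small number of array plasmids.
3. **Assembly** — an array sequence is ``signal + repeat + (spacer + repeat)``
   for each spacer: a 5′ export signal, then spacers interleaved with the
   direct repeat that Cas6 cleaves during pre-crRNA processing. The repeat
   and signal sequences are experiment-specific and must be supplied.
4. **Build planning** — a deterministic overlap-extension PCR plan: level-0
   fragments of 3–4 spacers in which adjacent fragments share exactly one
   spacer, joined pairwise up to ~12-spacer blocks; disjoint blocks are
   bridged by adding a one-spacer overhang before their join.

Coordinates are 0-based, half-open, on the sense strand; sequences are stored
as DNA 5′→3′.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .core import DesignError

__all__ = [
    "TargetTranscript",
    "SpacerDesign",
    "CrisprArray",
    "Fragment",
    "JoinStep",
    "FragmentPlan",
    "tile_spacers",
    "split_arrays",
    "assemble_array",
    "plan_fragments",
    "DEFAULT_SPACER_LEN",
    "DEFAULT_MAX_SPACERS",
]

DEFAULT_SPACER_LEN = 36
#: Default total-spacer budget per design (one experiment's full crRNA set).
DEFAULT_MAX_SPACERS = 48
#: Largest spacer block assembled by native-overlap joins; bigger designs are
#: split into blocks of at most this size, bridged by overhang additions.
BLOCK_SIZE = 12

_VALID = set("ACGTN")


@dataclass(frozen=True)
class TargetTranscript:
    """A sense-strand transcript with its 3′ UTR interval (0-based, half-open)."""

    name: str
    sequence: str
    utr_start: int
    utr_end: int

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", seq)
        if not set(seq) <= _VALID:
            bad = sorted(set(seq) - _VALID)
            raise DesignError(f"invalid characters in sequence: {bad}")
        if not 0 <= self.utr_start < self.utr_end <= len(seq):
            raise DesignError("UTR interval must lie within the sequence")

    @property
    def utr_sequence(self) -> str:
        return self.sequence[self.utr_start : self.utr_end]


@dataclass(frozen=True)
class SpacerDesign:
    """One spacer: its transcript window and its reverse-complement sequence."""

    index: int              # order along the UTR, 0-based
    window_start: int       # transcript coords, 0-based half-open
    window_end: int
    spacer: str             # 5'->3' crRNA spacer = revcomp(window)


@dataclass(frozen=True)
class CrisprArray:
    array_id: str
    signal: str
    repeat: str
    spacers: tuple[str, ...]

    @property
    def sequence(self) -> str:
        parts = [self.signal, self.repeat]
        for sp in self.spacers:
            parts.append(sp)
            parts.append(self.repeat)
        return "".join(parts)


@dataclass(frozen=True)
class Fragment:
    """A contiguous spacer span, 1-based inclusive on both ends."""

    first: int
    last: int

    @property
    def n_spacers(self) -> int:
        return self.last - self.first + 1

    def __str__(self) -> str:  # "spacers 4-6"
        return f"spacers {self.first}-{self.last}"


@dataclass(frozen=True)
class JoinStep:
    """One overlap-extension join; children overlap in exactly one spacer.

    When the children are natively disjoint, ``overhang_spacer`` records the
    spacer added to the left child as a PCR overhang to create the overlap.
    """

    left: Fragment
    right: Fragment
    product: Fragment
    overhang_spacer: int | None = None


@dataclass
class FragmentPlan:
    """Ordered overlap-extension build plan for one array."""

    n_spacers: int
    level0: list[Fragment] = field(default_factory=list)
    joins: list[JoinStep] = field(default_factory=list)

    def to_steps(self) -> list[dict]:
        """The plan as ordered, JSON-serialisable step records."""
        steps = [
            {"step": "amplify", "fragment": str(frag),
             "first": frag.first, "last": frag.last}
            for frag in self.level0
        ]
        for join in self.joins:
            if join.overhang_spacer is not None:
                steps.append({
                    "step": "add_overhang",
                    "fragment": str(join.left),
                    "overhang_spacer": join.overhang_spacer,
                })
            steps.append({
                "step": "join",
                "left": str(join.left),
                "right": str(join.right),
                "product": str(join.product),
            })
        return steps


# ---------------------------------------------------------------------------
# Tiling and splitting
# ---------------------------------------------------------------------------

def tile_spacers(
    transcript: TargetTranscript,
    spacer_len: int = DEFAULT_SPACER_LEN,
    gap: int = 0,
    max_spacers: int = DEFAULT_MAX_SPACERS,
) -> list[SpacerDesign]:
    """Tile non-overlapping spacer windows 5′→3′ along the 3′ UTR.

    Windows of ``spacer_len`` nt are placed from the UTR start at stride
    ``spacer_len + gap`` until the UTR end or ``max_spacers`` is reached.
    Windows containing ambiguous bases (N) are skipped with a warning. Each
    spacer is the exact reverse complement of its sense-strand window.
    """
    if spacer_len < 1:
        raise DesignError("spacer_len must be >= 1")
    if gap < 0:
        raise DesignError("gap must be >= 0")
    if max_spacers < 1:
        raise DesignError("max_spacers must be >= 1")
    utr_len = transcript.utr_end - transcript.utr_start
    if utr_len < spacer_len:
        raise DesignError(
            f"UTR ({utr_len} nt) is shorter than one spacer ({spacer_len} nt)"
        )
    designs: list[SpacerDesign] = []
    stride = spacer_len + gap
    pos = transcript.utr_start
    index = 0
    while pos + spacer_len <= transcript.utr_end and len(designs) < max_spacers:
        window = transcript.sequence[pos : pos + spacer_len]
        if "N" in window:
            warnings.warn(
                f"skipping window {pos}-{pos + spacer_len} with ambiguous bases",
                stacklevel=2,
            )
        else:
            spacer = str(Seq(window).reverse_complement())
            designs.append(SpacerDesign(index, pos, pos + spacer_len, spacer))
            index += 1
        pos += stride
    return designs


def split_arrays(
    spacers: list[SpacerDesign], n_arrays: int
) -> list[list[SpacerDesign]]:
    """Split spacers contiguously into ``n_arrays`` near-equal parts.

    Order is preserved and part sizes differ by at most one (earlier parts
    take the extra spacer).
    """
    if n_arrays < 1:
        raise DesignError("n_arrays must be >= 1")
    if n_arrays > len(spacers):
        raise DesignError("more arrays requested than spacers available")
    n = len(spacers)
    base, extra = divmod(n, n_arrays)
    parts: list[list[SpacerDesign]] = []
    start = 0
    for k in range(n_arrays):
        size = base + (1 if k < extra else 0)
        parts.append(spacers[start : start + size])
        start += size
    return parts


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def assemble_array(
    spacers: list[SpacerDesign] | list[str],
    repeat_seq: str,
    signal_seq: str = "",
    array_id: str = "array",
) -> CrisprArray:
    """Assemble the array sequence: signal + repeat + Σ(spacer + repeat)."""
    if not spacers:
        raise DesignError("cannot assemble an array with no spacers")
    if not repeat_seq:
        raise DesignError("repeat_seq must be nonempty")
    seqs = tuple(
        sp.spacer if isinstance(sp, SpacerDesign) else str(sp) for sp in spacers
    )
    return CrisprArray(
        array_id=array_id,
        signal=signal_seq.upper(),
        repeat=repeat_seq.upper(),
        spacers=tuple(s.upper() for s in seqs),
    )


# ---------------------------------------------------------------------------
# Build planning
# ---------------------------------------------------------------------------

def _split_block(first: int, last: int) -> tuple[list[Fragment], list[JoinStep]]:
    """Recursive overlap split of a <=12-spacer block into 3-4 spacer leaves.

    Left and right children share exactly one spacer, so their later join
    needs no overhang. Split sizes follow the worked build examples:
    5-7 spacers split directly into two leaves, 8-12 split near-evenly.
    """
    n = last - first + 1
    if n <= 4:
        return [Fragment(first, last)], []
    if n <= 7:
        left_size = {5: 3, 6: 4, 7: 4}[n]
    else:
        left_size = (n + 1) // 2
    mid = first + left_size - 1  # shared spacer
    left_frags, left_joins = _split_block(first, mid)
    right_frags, right_joins = _split_block(mid, last)
    product = Fragment(first, last)
    joins = left_joins + right_joins + [
        JoinStep(Fragment(first, mid), Fragment(mid, last), product)
    ]
    return left_frags + right_frags, joins


def _join_blocks(
    blocks: list[Fragment],
) -> list[JoinStep]:
    """Pairwise left-to-right joins of disjoint blocks via one-spacer overhangs."""
    joins: list[JoinStep] = []
    while len(blocks) > 1:
        next_level: list[Fragment] = []
        for k in range(0, len(blocks) - 1, 2):
            left, right = blocks[k], blocks[k + 1]
            product = Fragment(left.first, right.last)
            joins.append(
                JoinStep(left, right, product, overhang_spacer=right.first)
            )
            next_level.append(product)
        if len(blocks) % 2:
            next_level.append(blocks[-1])
        blocks = next_level
    return joins


def plan_fragments(n_spacers: int) -> FragmentPlan:
    """Plan the overlap-extension PCR build of an ``n_spacers`` array.

    Spacers are numbered 1..n. The array is partitioned into blocks of at
    most 12 spacers; within a block, level-0 fragments of 3-4 spacers share
    exactly one spacer with each neighbour and are joined pairwise. Disjoint
    blocks are then joined left-to-right, each join preceded by adding the
    right block's first spacer as an overhang to the left product, so every
    join again overlaps in exactly one spacer. Requires ``n_spacers >= 3``.
    """
    if isinstance(n_spacers, (list, tuple)):
        n_spacers = len(n_spacers)
    if isinstance(n_spacers, CrisprArray):
        n_spacers = len(n_spacers.spacers)
    if n_spacers < 3:
        raise DesignError("a build plan needs at least 3 spacers")

    n_blocks = -(-n_spacers // BLOCK_SIZE)  # ceil
    base, extra = divmod(n_spacers, n_blocks)
    blocks: list[Fragment] = []
    start = 1
    for k in range(n_blocks):
        size = base + (1 if k < extra else 0)
        blocks.append(Fragment(start, start + size - 1))
        start += size

    plan = FragmentPlan(n_spacers=n_spacers)
    for block in blocks:
        frags, joins = _split_block(block.first, block.last)
        plan.level0.extend(frags)
        plan.joins.extend(joins)
    plan.joins.extend(_join_blocks(blocks))
    return plan
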