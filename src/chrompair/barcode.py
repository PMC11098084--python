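"""Button barcode construction, encoding and editing.

A barcode is the chromosome-specific pattern of adhesive "button" nodes along
an arm.  Identity is carried solely by the gaps between buttons — exactly as
an industrial bar code carries information in bar widths — so the module
provides uniform and random layouts, the industrial "code 2 of 5" symbology
(every digit is five bars, exactly two of them wide), and the edits used in
rearrangement experiments: inversion (button/gap swap), distal shifts, and
reciprocal translocations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Barcode",
    "uniform_barcode",
    "random_barcode",
    "encode_2of5",
    "gaps_to_barcode",
    "barcode_to_gaps",
    "invert_barcode",
    "shift_barcode",
    "reciprocal_translocation",
    "read_barcode_file",
    "write_barcode_file",
    "CODE_2OF5_PATTERNS",
    "NARROW_GAP",
    "WIDE_GAP",
]

MIN_GAP = 2  # keeps cis rest separation (2 length units) above capture radius


@dataclass(frozen=True)
class Barcode:
    """Strictly increasing button node indices on an arm of given length."""

    button_indices: tuple
    arm_length: int

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.button_indices)
        object.__setattr__(self, "button_indices", idx)
        validate_barcode(self)

    @property
    def n_buttons(self) -> int:
        return len(self.button_indices)

    @property
    def span(self) -> tuple[int, int]:
        return self.button_indices[0], self.button_indices[-1]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.button_indices, dtype=np.int64)

    def min_gap(self) -> int:
        if self.n_buttons < 2:
            return self.arm_length
        return int(np.diff(self.as_array()).min())


def validate_barcode(bc: Barcode) -> None:
    idx = bc.button_indices
    if len(idx) == 0:
        raise ValueError("barcode must contain at least one button")
    if idx[0] < 0 or idx[-1] >= bc.arm_length:
        raise ValueError(f"button indices {idx} out of range [0, {bc.arm_length})")
    if any(b <= a for a, b in zip(idx, idx[1:])):
        raise ValueError("button indices must be strictly increasing")


def uniform_barcode(spacing: int, arm_length: int, start: int = 0) -> Barcode:
    """Buttons every ``spacing`` nodes from ``start`` to the end of the arm."""
    if spacing < MIN_GAP:
        raise ValueError(
            f"spacing must be >= {MIN_GAP} (adjacent cis buttons would sit "
            "inside the capture radius at rest)"
        )
    if not 0 <= start < arm_length:
        raise ValueError("start out of range")
    return Barcode(tuple(range(start, arm_length, spacing)), arm_length)


def _sample_spaced(
    rng: np.random.Generator, n: int, lo: int, hi: int, min_gap: int
) -> list[int]:
    """Uniform sample of n increasing indices in [lo, hi] with all consecutive
    differences >= min_gap, via the standard gap-removing bijection."""
    m = (hi - lo + 1) - (n - 1) * (min_gap - 1)
    if m < n:
        raise ValueError(
            f"cannot place {n} buttons with min_gap {min_gap} in [{lo}, {hi}]"
        )
    picks = np.sort(rng.choice(m, size=n, replace=False))
    return [lo + int(p) + i * (min_gap - 1) for i, p in enumerate(picks)]


def random_barcode(
    n_buttons: int,
    node_range: tuple[int, int],
    rng: np.random.Generator,
    min_gap: int = MIN_GAP,
    arm_length: int | None = None,
    fix_endpoints: bool = False,
) -> Barcode:
    """Random button layout, uniform over all admissible layouts.

    ``node_range`` is the inclusive index interval the buttons must lie in.
    With ``fix_endpoints`` both interval endpoints are forced to be buttons
    (used when comparing codes "distributed with the same endpoints").
    """
    lo, hi = int(node_range[0]), int(node_range[1])
    if arm_length is None:
        arm_length = hi + 1
    if lo < 0 or hi >= arm_length or lo > hi:
        raise ValueError("invalid node_range")
    if n_buttons < 1:
        raise ValueError("n_buttons must be >= 1")
    if fix_endpoints:
        if n_buttons < 2:
            raise ValueError("fix_endpoints requires at least 2 buttons")
        interior = (
            _sample_spaced(rng, n_buttons - 2, lo + min_gap, hi - min_gap, min_gap)
            if n_buttons > 2
            else []
        )
        idx = [lo, *interior, hi]
        if any(b - a < min_gap for a, b in zip(idx, idx[1:])):
            raise ValueError("cannot satisfy min_gap with fixed endpoints")
    else:
        idx = _sample_spaced(rng, n_buttons, lo, hi, min_gap)
    return Barcode(tuple(idx), arm_length)


NARROW_GAP = 2  # nodes between buttons for a narrow bar
WIDE_GAP = 6  # nodes between buttons for a wide bar (3x the narrow width)

# Standard industrial "code 2 of 5" bar patterns (W = wide, N = narrow).
# Digits 1-9 carry weights 1-2-4-7 plus an even-parity bar; 0 is the 4+7
# word.  Any ten-word table with exactly two wide bars of five would encode
# equally well; this is the published symbology.
CODE_2OF5_PATTERNS: dict[int, str] = {
    0: "NNWWN",
    1: "WNNNW",
    2: "NWNNW",
    3: "WWNNN",
    4: "NNWNW",
    5: "WNWNN",
    6: "NWWNN",
    7: "NNNWW",
    8: "WNNWN",
    9: "NWNWN",
}


def encode_2of5(digit: int) -> list[int]:
    """Gap sequence (five gaps, each 2 or 6 nodes) encoding one decimal digit.

    Wide bars map to 6-node gaps and narrow bars to 2-node gaps, so every
    digit spans 2·6 + 3·2 = 18 nodes between its first and last button.
    """
    if digit not in CODE_2OF5_PATTERNS:
        raise ValueError(f"digit must be in 0..9, got {digit!r}")
    return [WIDE_GAP if bar == "W" else NARROW_GAP for bar in CODE_2OF5_PATTERNS[digit]]


def gaps_to_barcode(gaps, start: int, arm_length: int) -> Barcode:
    """Buttons at cumulative positions; k gaps yield k+1 buttons."""
    gaps = [int(g) for g in gaps]
    if any(g < MIN_GAP for g in gaps):
        raise ValueError(f"all gaps must be >= {MIN_GAP}")
    idx = np.concatenate([[start], start + np.cumsum(gaps)]) if gaps else np.array([start])
    if idx[-1] >= arm_length:
        raise ValueError("barcode exceeds arm length")
    return Barcode(tuple(int(i) for i in idx), arm_length)


def barcode_to_gaps(bc: Barcode) -> list[int]:
    return [int(g) for g in np.diff(bc.as_array())]


def invert_barcode(bc: Barcode, span: tuple[int, int] | None = None) -> Barcode:
    """Swap buttons and gaps over a node interval.

    Every node in ``span`` (default: [first button, last button]) that was a
    button becomes non-button and vice versa, turning gaps into tracts of
    pairing sites.  Applying it twice over the same explicit span restores
    the original.
    """
    lo, hi = bc.span if span is None else (int(span[0]), int(span[1]))
    members = set(bc.button_indices)
    inverted = tuple(i for i in range(lo, hi + 1) if i not in members)
    if not inverted:
        raise ValueError("inversion of a gap-free barcode yields no buttons")
    return Barcode(inverted, bc.arm_length)


def shift_barcode(bc: Barcode, offset: int) -> Barcode:
    """Translate every button by ``offset`` nodes (distal when positive)."""
    idx = tuple(i + int(offset) for i in bc.button_indices)
    if idx[0] < 0 or idx[-1] >= bc.arm_length:
        raise ValueError(
            f"shift by {offset} moves buttons outside [0, {bc.arm_length})"
        )
    return Barcode(idx, bc.arm_length)


def reciprocal_translocation(
    barcode_a: Barcode,
    barcode_b: Barcode,
    node_range_a: tuple[int, int],
    node_range_b: tuple[int, int],
) -> tuple[Barcode, Barcode]:
    """Exchange button/non-button status between two equal-length node ranges.

    Ranges are inclusive ``(start, end)`` intervals; position ``start_a + k``
    on chromosome A swaps status with ``start_b + k`` on chromosome B.
    Swapping each chromosome's full patch exchanges the entire codes.
    """
    lo_a, hi_a = map(int, node_range_a)
    lo_b, hi_b = map(int, node_range_b)
    if hi_a - lo_a != hi_b - lo_b:
        raise ValueError("node ranges must have equal length")
    if lo_a < 0 or hi_a >= barcode_a.arm_length or lo_b < 0 or hi_b >= barcode_b.arm_length:
        raise ValueError("node range out of arm bounds")
    set_a, set_b = set(barcode_a.button_indices), set(barcode_b.button_indices)
    new_a, new_b = set(set_a), set(set_b)
    for k in range(hi_a - lo_a + 1):
        pa, pb = lo_a + k, lo_b + k
        a_has, b_has = pa in set_a, pb in set_b
        if b_has:
            new_a.add(pa)
        else:
            new_a.discard(pa)
        if a_has:
            new_b.add(pb)
        else:
            new_b.discard(pb)
    return (
        Barcode(tuple(sorted(new_a)), barcode_a.arm_length),
        Barcode(tuple(sorted(new_b)), barcode_b.arm_length),
    )


def write_barcode_file(barcodes: dict, path) -> None:
    """One line per chromosome: ``chrom_id: i1,i2,...,ik / arm_length``."""
    with open(path, "w") as fh:
        for chrom_id, bc in barcodes.items():
            idx = ",".join(str(i) for i in bc.button_indices)
            fh.write(f"{chrom_id}: {idx} / {bc.arm_length}\n")


def read_barcode_file(path) -> dict:
    barcodes: dict[str, Barcode] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                chrom_id, rest = line.split(":", 1)
                idx_part, arm_part = rest.split("/")
                idx = tuple(int(t) for t in idx_part.strip().split(","))
                barcodes[chrom_id.strip()] = Barcode(idx, int(arm_part))
            except ValueError as exc:
                raise ValueError(f"{path}:{line_no}: malformed barcode line") from exc
    return barcodes
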