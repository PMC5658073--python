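"""Closed integer-nm wavelength intervals and set operations on them.

A RegionSet is an ordered list of disjoint closed intervals [lo, hi] in nm,
used for significant-correlation regions, exclusion masks (device noise,
water/atmosphere bands) and selected sensitive bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import GRID_MAX_NM, GRID_MIN_NM


@dataclass(frozen=True, order=True)
class Region:
    lo: int
    hi: int

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError(f"region lo {self.lo} > hi {self.hi}")
        if self.lo < GRID_MIN_NM or self.hi > GRID_MAX_NM:
            raise ValueError(
                f"region [{self.lo}, {self.hi}] outside {GRID_MIN_NM}-{GRID_MAX_NM} nm"
            )

    @property
    def width(self) -> int:
        """Number of integer wavelengths in the closed interval."""
        return self.hi - self.lo + 1

    @property
    def center(self) -> float:
        return (self.lo + self.hi) / 2.0

    def contains(self, nm: float) -> bool:
        return self.lo <= nm <= self.hi

    def overlaps(self, other: "Region") -> bool:
        return self.lo <= other.hi and other.lo <= self.hi

    def __str__(self) -> str:  # e.g. "537-560 nm"
        return f"{self.lo}-{self.hi} nm"


@dataclass
class RegionSet:
    """Disjoint, ascending closed intervals on the integer nm grid."""

    regions: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.regions = [
            r if isinstance(r, Region) else Region(int(r[0]), int(r[1]))
            for r in self.regions
        ]
        self.regions.sort()
        for a, b in zip(self.regions, self.regions[1:]):
            if a.hi >= b.lo:
                raise ValueError(f"overlapping regions {a} and {b}")

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def __bool__(self) -> bool:
        return bool(self.regions)

    def contains(self, nm: float) -> bool:
        return any(r.contains(nm) for r in self.regions)

    def wavelengths(self) -> list[int]:
        """All integer wavelengths covered, ascending."""
        out: list[int] = []
        for r in self.regions:
            out.extend(range(r.lo, r.hi + 1))
        return out

    def difference(self, other: "RegionSet", min_width: int = 1) -> "RegionSet":
        """Set difference; surviving fragments narrower than min_width dropped."""
        pieces: list[Region] = []
        for r in self.regions:
            cur = [(r.lo, r.hi)]
            for ex in other.regions:
                nxt: list[tuple[int, int]] = []
                for lo, hi in cur:
                    if ex.hi < lo or ex.lo > hi:
                        nxt.append((lo, hi))
                        continue
                    if ex.lo > lo:
                        nxt.append((lo, ex.lo - 1))
                    if ex.hi < hi:
                        nxt.append((ex.hi + 1, hi))
                cur = nxt
            pieces.extend(Region(lo, hi) for lo, hi in cur)
        pieces = [p for p in pieces if p.width >= min_width]
        return RegionSet(pieces)

    @staticmethod
    def merged(intervals: list[tuple[int, int]]) -> "RegionSet":
        """Build from possibly overlapping/touching intervals by merging."""
        if not intervals:
            return RegionSet([])
        items = sorted((int(a), int(b)) for a, b in intervals)
        out = [list(items[0])]
        for lo, hi in items[1:]:
            if lo <= out[-1][1] + 1:
                out[-1][1] = max(out[-1][1], hi)
            else:
                out.append([lo, hi])
        return RegionSet([Region(lo, hi) for lo, hi in out])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("lo_nm\thi_nm\n")
            for r in self.regions:
                fh.write(f"{r.lo}\t{r.hi}\n")


# Regions dropped before modeling: short-wave device noise plus the two
# water/atmosphere absorption bands.
DEFAULT_EXCLUSIONS = RegionSet([(350, 400), (1362, 1458), (1834, 1895)])
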