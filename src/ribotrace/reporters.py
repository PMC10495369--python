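"""Reporter ORF geometry.

A reporter is described entirely in codon coordinates (1-based, inclusive;
one codon = one amino acid = 3 nt).  A design partitions the ORF into
ordered regions -- epitope cassettes, the repeat (or control) insert, and
plain flanking sequence -- and lists the codon positions at which each
fluorescent epitope is *completed* (the epitope becomes visible the moment
the ribosome has translated its last codon).

Two topologies are supported:

* one-color elongation reporters: an N-terminal epitope cassette, the
  insert, and a C-terminal flank; the ribosome terminates at the end of
  the ORF (``ch1_stop == total_length``).
* two-color frameshift reporters: a channel-1 cassette upstream of the
  insert and a channel-2 cassette downstream, with the normal reading
  frame terminating at a stop codon just after the insert
  (``ch1_stop == insert end``); channel 2 is only reached by ribosomes
  that shift frame inside the insert (or by cap-independent initiation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["Region", "ReporterDesign", "build_reporter", "PRESETS"]

_ROLES = {"epitope_cassette", "insert", "flank"}
_CH2_MODES = {"frameshift", "ran_initiation", "in_frame"}


class LayoutError(ValueError):
    """Raised when a reporter layout violates its geometric invariants."""


@dataclass(frozen=True)
class Region:
    label: str
    start: int  # codon, 1-based inclusive
    end: int    # codon, inclusive
    role: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ReporterDesign:
    name: str
    total_length: int
    regions: tuple[Region, ...]
    epitope_positions_ch1: tuple[int, ...]
    epitope_positions_ch2: tuple[int, ...] = ()
    ch1_stop: int = 0
    ch2_reachable_only_by: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "regions", tuple(self.regions))
        object.__setattr__(
            self, "epitope_positions_ch1", tuple(int(p) for p in self.epitope_positions_ch1)
        )
        object.__setattr__(
            self, "epitope_positions_ch2", tuple(int(p) for p in self.epitope_positions_ch2)
        )
        if self.ch1_stop == 0:
            object.__setattr__(self, "ch1_stop", self.total_length)
        self._validate()

    # -- validation ---------------------------------------------------
    def _validate(self) -> None:
        if self.total_length < 1:
            raise LayoutError("total_length must be >= 1")
        covered = 0
        prev_end = 0
        for r in self.regions:
            if r.role not in _ROLES:
                raise LayoutError(f"unknown region role {r.role!r}")
            if not (0 < r.start <= r.end <= self.total_length):
                raise LayoutError(f"region {r.label!r} bounds out of range")
            if r.start != prev_end + 1:
                raise LayoutError(
                    f"regions must tile the ORF without gaps/overlap; "
                    f"{r.label!r} starts at {r.start}, expected {prev_end + 1}"
                )
            prev_end = r.end
            covered += r.length
        if covered != self.total_length or prev_end != self.total_length:
            raise LayoutError("regions do not tile [1, total_length]")

        for chan, eps in (("ch1", self.epitope_positions_ch1), ("ch2", self.epitope_positions_ch2)):
            if list(eps) != sorted(set(eps)):
                raise LayoutError(f"{chan} epitope positions must be strictly increasing")
            for p in eps:
                if not any(
                    r.role == "epitope_cassette" and r.start <= p <= r.end for r in self.regions
                ):
                    raise LayoutError(f"{chan} epitope at codon {p} outside any epitope cassette")

        if not self.ch2_reachable_only_by <= _CH2_MODES:
            raise LayoutError(f"bad ch2 access flags {set(self.ch2_reachable_only_by)!r}")

        if self.two_color:
            ins = self.insert_region
            if ins is None:
                raise LayoutError("two-color design requires an insert region")
            if any(p >= ins.start for p in self.epitope_positions_ch1):
                raise LayoutError("ch1 epitopes must all lie upstream of the insert")
            if any(p <= ins.end for p in self.epitope_positions_ch2):
                raise LayoutError("ch2 epitopes must all lie downstream of the insert")

        if not (1 <= self.ch1_stop <= self.total_length):
            raise LayoutError("ch1_stop out of range")

    # -- convenience --------------------------------------------------
    @property
    def two_color(self) -> bool:
        return len(self.epitope_positions_ch2) > 0

    @property
    def insert_region(self) -> Region | None:
        for r in self.regions:
            if r.role == "insert":
                return r
        return None

    @property
    def insert_length(self) -> int:
        r = self.insert_region
        return 0 if r is None else r.length

    @property
    def flank_length(self) -> int:
        """Codons outside the insert translated by a non-shifted ribosome (L0)."""
        ins = self.insert_region
        if ins is None:
            return self.ch1_stop
        n_in = max(0, min(self.ch1_stop, ins.end) - ins.start + 1)
        return self.ch1_stop - n_in

    def region_speed_map(self, v_flank: float, v_insert: float) -> np.ndarray:
        """Per-codon elongation speed array (index 0 = codon 1)."""
        v = np.full(self.total_length, float(v_flank))
        ins = self.insert_region
        if ins is not None:
            v[ins.start - 1 : ins.end] = float(v_insert)
        return v


def _one_color(name: str, cassette: int, insert: int, tail: int, n_epitopes: int = 24) -> ReporterDesign:
    regions = [Region("cassette_ch1", 1, cassette, "epitope_cassette")]
    pos = cassette
    if insert > 0:
        regions.append(Region("insert", cassette + 1, cassette + insert, "insert"))
        pos = cassette + insert
    if tail > 0:
        regions.append(Region("flank", pos + 1, pos + tail, "flank"))
        pos = pos + tail
    eps = tuple(np.linspace(cassette / n_epitopes, cassette, n_epitopes).round().astype(int))
    return ReporterDesign(
        name=name,
        total_length=pos,
        regions=tuple(regions),
        epitope_positions_ch1=eps,
        ch1_stop=pos,
        ch2_reachable_only_by=frozenset(),
    )


def _two_color(name: str, cassette1: int, insert: int, cassette2: int, n_epitopes: int = 24) -> ReporterDesign:
    regions = (
        Region("cassette_ch1", 1, cassette1, "epitope_cassette"),
        Region("insert", cassette1 + 1, cassette1 + insert, "insert"),
        Region("cassette_ch2", cassette1 + insert + 1, cassette1 + insert + cassette2, "epitope_cassette"),
    )
    eps1 = tuple(np.linspace(cassette1 / n_epitopes, cassette1, n_epitopes).round().astype(int))
    off = cassette1 + insert
    eps2 = tuple(off + np.linspace(cassette2 / n_epitopes, cassette2, n_epitopes).round().astype(int))
    return ReporterDesign(
        name=name,
        total_length=cassette1 + insert + cassette2,
        regions=regions,
        epitope_positions_ch1=eps1,
        epitope_positions_ch2=eps2,
        ch1_stop=cassette1 + insert,  # stop codon directly after the insert
        ch2_reachable_only_by=frozenset({"frameshift", "ran_initiation"}),
    )


# The elongation reporters: a 3009 nt (1003 codon) ORF of which the
# (GGGGCC)70 repeat contributes 420 nt (140 codons); the remaining 863
# codons split into the 24-epitope cassette (477 codons, the size of a
# 24x epitope array) and the downstream degron flank (386 codons).  The
# control construct replaces the repeat with a 513 nt (171 codon)
# luciferase insert.
_CASSETTE = 477
_TAIL = 863 - _CASSETTE

PRESETS = {
    "elongation_GGGGCC70": lambda: _one_color("elongation_GGGGCC70", _CASSETTE, 140, _TAIL),
    "elongation_NLuc": lambda: _one_color("elongation_NLuc", _CASSETTE, 171, _TAIL),
    "frameshift_twocolor": lambda: _two_color("frameshift_twocolor", _CASSETTE, 140, _CASSETTE),
}


def build_reporter(spec) -> ReporterDesign:
    """Return a validated reporter design.

    ``spec`` is either a preset name (see ``PRESETS``) or an already
    constructed :class:`ReporterDesign` / mapping of its fields.
    """
    if isinstance(spec, ReporterDesign):
        return spec
    if isinstance(spec, str):
        try:
            return PRESETS[spec]()
        except KeyError:
            raise LayoutError(
                f"unknown preset {spec!r}; known presets: {sorted(PRESETS)}"
            ) from None
    if isinstance(spec, dict):
        regions = tuple(
            r if isinstance(r, Region) else Region(*r) for r in spec["regions"]
        )
        return ReporterDesign(
            name=spec.get("name", "custom"),
            total_length=spec["total_length"],
            regions=regions,
            epitope_positions_ch1=tuple(spec.get("epitope_positions_ch1", ())),
            epitope_positions_ch2=tuple(spec.get("epitope_positions_ch2", ())),
            ch1_stop=spec.get("ch1_stop", 0),
            ch2_reachable_only_by=frozenset(spec.get("ch2_reachable_only_by", ())),
        )
    raise TypeError(f"cannot build a reporter from {type(spec).__name__}")
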