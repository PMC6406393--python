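"""Treatment protocols: piecewise-constant ADT / AR-overexpression signals.

A protocol is an ordered list of contiguous, non-overlapping segments
``(t_start, t_end, u_ADT, u_OE)`` in hours, left-closed/right-open. The
two controls are fractions in [0, 1]:

* ``u_ADT`` — androgen-deprivation efficacy; multiplies AR production by
  ``1 - u_ADT`` (1 = full ADT).
* ``u_OE`` — AR-overexpression drive used by bipolar androgen treatment
  (BAT); adds ``beta_OE * u_OE`` to AR production.

Queries outside the listed segments return the no-treatment pair (0, 0),
so any protocol implicitly covers the whole simulation span.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterator

import yaml

__all__ = [
    "Protocol", "ProtocolError", "no_treatment", "constant_adt",
    "intermittent_adt", "bat", "parse_protocol_spec",
]

#: two weeks in hours — the BAT block length
TWO_WEEKS_H = 336.0


class ProtocolError(ValueError):
    """Malformed protocol definition."""


@dataclass(frozen=True)
class Segment:
    t_start: float
    t_end: float
    u_adt: float
    u_oe: float

    def __post_init__(self):
        if not self.t_end > self.t_start:
            raise ProtocolError("segment must have t_end > t_start")
        for u in (self.u_adt, self.u_oe):
            if not 0.0 <= u <= 1.0:
                raise ProtocolError("treatment fractions must lie in [0, 1]")


@dataclass(frozen=True)
class Protocol:
    """Ordered piecewise-constant treatment signal."""

    segments: tuple[Segment, ...]
    label: str = ""
    _starts: tuple[float, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        segs = tuple(self.segments)
        for a, b in zip(segs, segs[1:]):
            if b.t_start < a.t_end - 1e-12:
                raise ProtocolError("segments overlap")
        object.__setattr__(self, "segments", segs)
        object.__setattr__(self, "_starts", tuple(s.t_start for s in segs))

    def u_at(self, t: float) -> tuple[float, float]:
        """(u_ADT, u_OE) at time ``t``; O(log n) bisection lookup."""
        i = bisect.bisect_right(self._starts, t) - 1
        if i >= 0:
            s = self.segments[i]
            if s.t_start <= t < s.t_end:
                return s.u_adt, s.u_oe
        return 0.0, 0.0

    def iter_segments(self, t0: float, t1: float
                      ) -> Iterator[tuple[float, float, float, float]]:
        """Contiguous constant-control pieces covering [t0, t1].

        Gaps between (or outside) listed segments are yielded as
        no-treatment pieces, so consumers can integrate piecewise.
        """
        if not t1 > t0:
            raise ProtocolError("need t1 > t0")
        cursor = t0
        for s in self.segments:
            if s.t_end <= cursor or s.t_start >= t1:
                continue
            if s.t_start > cursor:
                yield (cursor, min(s.t_start, t1), 0.0, 0.0)
                cursor = min(s.t_start, t1)
            hi = min(s.t_end, t1)
            yield (max(s.t_start, cursor), hi, s.u_adt, s.u_oe)
            cursor = hi
            if cursor >= t1:
                break
        if cursor < t1:
            yield (cursor, t1, 0.0, 0.0)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "segments": [
                {"t_start": s.t_start, "t_end": s.t_end,
                 "u_ADT": s.u_adt, "u_OE": s.u_oe}
                for s in self.segments
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Protocol":
        segs = tuple(
            Segment(float(s["t_start"]), float(s["t_end"]),
                    float(s.get("u_ADT", 0.0)), float(s.get("u_OE", 0.0)))
            for s in d.get("segments", ())
        )
        return cls(segments=segs, label=str(d.get("label", "")))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Protocol":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def no_treatment(label: str = "none") -> Protocol:
    """The null protocol: u_ADT = u_OE = 0 everywhere."""
    return Protocol(segments=(), label=label)


def constant_adt(t_on: float = 0.0, u: float = 1.0, t_end: float = 1e6) -> Protocol:
    """Continuous ADT at efficacy ``u`` from ``t_on`` onward."""
    if t_on < 0:
        raise ProtocolError("t_on must be >= 0")
    if not 0.0 <= u <= 1.0:
        raise ProtocolError("u must lie in [0, 1]")
    if u == 0.0:
        return no_treatment(label=f"adt:t_on={t_on:g},u=0")
    return Protocol(
        segments=(Segment(t_on, t_end, u, 0.0),),
        label=f"adt:t_on={t_on:g},u={u:g}",
    )


def intermittent_adt(on_duration: float = 168.0, off_duration: float = 168.0,
                     t_start: float = 0.0, n_cycles: int = 4) -> Protocol:
    """Periodic ADT blocks separated by drug-holiday periods.

    Each cycle is ``on_duration`` hours of full ADT followed by
    ``off_duration`` hours untreated; defaults are one week on, one week
    off.
    """
    if on_duration <= 0 or off_duration <= 0:
        raise ProtocolError("durations must be positive")
    if n_cycles < 1:
        raise ProtocolError("n_cycles must be >= 1 (empty protocol)")
    segs = []
    t = t_start
    for _ in range(n_cycles):
        segs.append(Segment(t, t + on_duration, 1.0, 0.0))
        t += on_duration + off_duration
    return Protocol(
        segments=tuple(segs),
        label=f"iadt:on={on_duration:g},off={off_duration:g},n={n_cycles}",
    )


def bat(block: float = TWO_WEEKS_H, t_start: float = 0.0,
        n_cycles: int = 3) -> Protocol:
    """Bipolar androgen treatment: alternating AR overexpression and ADT.

    Each cycle is one ``block`` (default two weeks) of AR overexpression
    (u_OE = 1) followed by one block of full ADT (u_ADT = 1); the two
    controls are never active simultaneously.
    """
    if block <= 0:
        raise ProtocolError("block must be positive")
    if n_cycles < 1:
        raise ProtocolError("n_cycles must be >= 1 (empty protocol)")
    segs = []
    t = t_start
    for _ in range(n_cycles):
        segs.append(Segment(t, t + block, 0.0, 1.0))
        segs.append(Segment(t + block, t + 2 * block, 1.0, 0.0))
        t += 2 * block
    return Protocol(segments=tuple(segs), label=f"bat:block={block:g},n={n_cycles}")


def parse_protocol_spec(spec: str) -> Protocol:
    """Parse CLI shorthand like ``adt:t_on=500``, ``iadt:on=168,off=168``,
    ``bat``, ``bat:block=336,n=3`` or ``none``."""
    name, _, rest = spec.partition(":")
    kw = {}
    if rest:
        for item in rest.split(","):
            k, _, v = item.partition("=")
            kw[k.strip()] = float(v)
    name = name.strip().lower()
    if name in ("none", "no-treatment"):
        return no_treatment()
    if name == "adt":
        return constant_adt(t_on=kw.get("t_on", 0.0), u=kw.get("u", 1.0))
    if name == "iadt":
        return intermittent_adt(on_duration=kw.get("on", 168.0),
                                off_duration=kw.get("off", 168.0),
                                t_start=kw.get("t_start", 0.0),
                                n_cycles=int(kw.get("n", 4)))
    if name == "bat":
        return bat(block=kw.get("block", TWO_WEEKS_H),
                   t_start=kw.get("t_start", 0.0),
                   n_cycles=int(kw.get("n", 3)))
    raise ProtocolError(f"unknown protocol spec {spec!r}")
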