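"""Putative G-quadruplex (pG4) motif scanning.

A pG4 motif is four runs ("tracts") of at least ``g`` consecutive guanines
separated by three loops of bounded length — the quadparser-style pattern
``G{g,}(N{lmin,lmax}G{g,}){3}``. Three stringency presets are provided:

* ``G3L1-7`` — four G3+ tracts, loops 1–7 nt (the canonical, "mid" stringency);
* ``G3L1-5`` — four G3+ tracts, loops 1–5 nt (high stringency);
* ``G2L1-10`` — four G2+ tracts, loops 1–10 nt (low stringency, admits
  two-quartet quadruplexes and long loops).

Matching policy (documented so that counts are reproducible): hits are the
leftmost, shortest (lazy) non-overlapping occurrences of the pattern, and the
scan resumes immediately after each hit's end. Tracts may sit inside longer
G-runs and loops may themselves contain guanines; ``N`` never counts as G but
is legal in loops. ``T`` and ``U`` are equivalent and matching is
case-insensitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

_ALLOWED = frozenset("ACGTN")
_RC_TABLE = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


class SequenceAlphabetError(ValueError):
    """Raised when a sequence contains a character outside {A,C,G,T,U,N}."""


@dataclass(frozen=True)
class StringencyPreset:
    """A pG4 search stringency.

    Parameters
    ----------
    name:
        Label of the preset (e.g. ``"G3L1-7"``).
    g:
        Minimum number of consecutive guanines per tract (>= 2).
    loop_min, loop_max:
        Inclusive bounds on loop length in nucleotides.
    n_tracts:
        Number of G-tracts; 4 for an intramolecular quadruplex.
    """

    name: str
    g: int
    loop_min: int
    loop_max: int
    n_tracts: int = 4

    def __post_init__(self) -> None:
        if self.g < 2:
            raise ValueError(f"tract length g must be >= 2, got {self.g}")
        if not (1 <= self.loop_min <= self.loop_max):
            raise ValueError(
                f"need 1 <= loop_min <= loop_max, got [{self.loop_min}, {self.loop_max}]"
            )
        if self.n_tracts < 4:
            raise ValueError(f"n_tracts must be >= 4, got {self.n_tracts}")

    @property
    def min_length(self) -> int:
        """Length of the shortest sequence the preset can match."""
        return self.n_tracts * self.g + (self.n_tracts - 1) * self.loop_min


PRESETS: dict[str, StringencyPreset] = {
    p.name: p
    for p in (
        StringencyPreset("G3L1-7", g=3, loop_min=1, loop_max=7),
        StringencyPreset("G3L1-5", g=3, loop_min=1, loop_max=5),
        StringencyPreset("G2L1-10", g=2, loop_min=1, loop_max=10),
    )
}
DEFAULT_PRESET = PRESETS["G3L1-7"]


def get_preset(name: str | StringencyPreset) -> StringencyPreset:
    """Resolve a preset by name (or pass a preset through unchanged)."""
    if isinstance(name, StringencyPreset):
        return name
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None


@dataclass(frozen=True)
class MotifHit:
    """One non-overlapping pG4 occurrence, 0-based half-open coordinates."""

    transcript_id: str
    start: int
    end: int
    tract_starts: tuple[int, ...]
    loop_lengths: tuple[int, ...]
    matched_sequence: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.matched_sequence):
            raise ValueError("end - start must equal matched sequence length")


def _normalize(sequence: str) -> str:
    """Uppercase, map U->T, and reject characters outside the alphabet."""
    s = sequence.upper().replace("U", "T")
    if not set(s) <= _ALLOWED:
        for i, ch in enumerate(s):
            if ch not in _ALLOWED:
                raise SequenceAlphabetError(
                    f"illegal character {sequence[i]!r} at position {i}"
                )
    return s


def reverse_complement(sequence: str) -> str:
    """Reverse complement (DNA alphabet output; U treated as T)."""
    return sequence.translate(_RC_TABLE)[::-1]


def scan_pg4(
    sequence: str,
    preset: str | StringencyPreset = DEFAULT_PRESET,
    transcript_id: str = "seq",
) -> list[MotifHit]:
    """Scan one strand of ``sequence`` for non-overlapping pG4 motifs.

    Returns the leftmost-shortest non-overlapping occurrences: at each
    position the earliest full match is taken with the minimal possible end
    (lazy tracts and loops), and scanning resumes after that end. The empty
    sequence yields an empty list.
    """
    preset = get_preset(preset)
    s = _normalize(sequence)
    n = len(s)
    if n < preset.min_length:
        return []

    # run[i] = length of the maximal G-run starting at i
    run = [0] * (n + 1)
    for i in range(n - 1, -1, -1):
        run[i] = run[i + 1] + 1 if s[i] == "G" else 0

    g, lmin, lmax, k = preset.g, preset.loop_min, preset.loop_max, preset.n_tracts
    memo: dict[tuple[int, int], int | None] = {}

    def min_end(pos: int, tracts: int) -> int | None:
        """Minimal end of ``tracts`` tracts (loops between) starting at pos."""
        key = (pos, tracts)
        if key in memo:
            return memo[key]
        best: int | None = None
        r = run[pos]
        if r >= g:
            if tracts == 1:
                best = pos + g
            else:
                for t in range(g, r + 1):
                    base = pos + t
                    for loop in range(lmin, lmax + 1):
                        nxt = base + loop
                        if nxt >= n:
                            break
                        e = min_end(nxt, tracts - 1)
                        if e is not None and (best is None or e < best):
                            best = e
        memo[key] = best
        return best

    def reconstruct(pos: int, tracts: int, target: int) -> tuple[list[int], list[int]]:
        """Recover tract starts and loop lengths of the minimal-end match."""
        tract_starts = [pos]
        loops: list[int] = []
        while tracts > 1:
            r = run[pos]
            advanced = False
            for t in range(g, r + 1):
                base = pos + t
                for loop in range(lmin, lmax + 1):
                    nxt = base + loop
                    if nxt >= n:
                        break
                    if min_end(nxt, tracts - 1) == target:
                        loops.append(loop)
                        pos = nxt
                        tract_starts.append(pos)
                        tracts -= 1
                        advanced = True
                        break
                if advanced:
                    break
            if not advanced:  # pragma: no cover - guarded by min_end
                raise AssertionError("match reconstruction failed")
        return tract_starts, loops

    hits: list[MotifHit] = []
    pos = 0
    while pos <= n - preset.min_length:
        if run[pos] >= g:
            end = min_end(pos, k)
            if end is not None:
                tract_starts, loops = reconstruct(pos, k, end)
                hits.append(
                    MotifHit(
                        transcript_id=transcript_id,
                        start=pos,
                        end=end,
                        tract_starts=tuple(tract_starts),
                        loop_lengths=tuple(loops),
                        matched_sequence=sequence[pos:end],
                    )
                )
                pos = end
                continue
        pos += 1
    return hits


def scan_pg4_both_strands(
    sequence: str,
    preset: str | StringencyPreset = DEFAULT_PRESET,
    transcript_id: str = "seq",
) -> list[MotifHit]:
    """Scan both strands (genomic DNA use).

    Minus-strand hits carry forward-strand ``start``/``end`` coordinates;
    their ``tract_starts``/``loop_lengths`` describe the motif as read on the
    minus strand and ``matched_sequence`` is the minus-strand segment.
    """
    hits = scan_pg4(sequence, preset, transcript_id)
    n = len(sequence)
    for h in scan_pg4(reverse_complement(sequence), preset, transcript_id):
        hits.append(
            MotifHit(
                transcript_id=transcript_id,
                start=n - h.end,
                end=n - h.start,
                tract_starts=h.tract_starts,
                loop_lengths=h.loop_lengths,
                matched_sequence=h.matched_sequence,
                strand="-",
            )
        )
    return sorted(hits, key=lambda h: (h.start, h.strand))


def count_pg4(sequence: str, preset: str | StringencyPreset = DEFAULT_PRESET) -> int:
    """Number of non-overlapping pG4 hits on the given strand."""
    return len(scan_pg4(sequence, preset))


def pg4_density(count: int, length: int) -> float:
    """Motifs per nucleotide: the count/length density ratio."""
    if length <= 0:
        raise ValueError(f"length must be positive, got {length}")
    if count < 0:
        raise ValueError(f"count must be nonnegative, got {count}")
    return count / length


def gc_content(sequence: str) -> float:
    """Fraction of G+C over the full sequence length (N counts in the denominator)."""
    s = _normalize(sequence)
    if not s:
        raise ValueError("gc_content of an empty sequence is undefined")
    return (s.count("G") + s.count("C")) / len(s)


@dataclass
class TranscriptRecord:
    """A transcript sequence with its derived pG4 features."""

    id: str
    sequence: str
    length: int
    gc_fraction: float
    pg4_counts: dict[str, int] = field(default_factory=dict)
    pg4_density: dict[str, float] = field(default_factory=dict)
    biotype: str | None = None

    @classmethod
    def from_sequence(
        cls,
        id: str,
        sequence: str,
        presets: Iterable[str | StringencyPreset] | None = None,
        biotype: str | None = None,
    ) -> "TranscriptRecord":
        presets = [get_preset(p) for p in (presets or PRESETS.values())]
        counts = {p.name: count_pg4(sequence, p) for p in presets}
        length = len(sequence)
        return cls(
            id=id,
            sequence=sequence,
            length=length,
            gc_fraction=gc_content(sequence),
            pg4_counts=counts,
            pg4_density={name: pg4_density(c, length) for name, c in counts.items()},
            biotype=biotype,
        )


def features_table(records: Sequence[TranscriptRecord]) -> pd.DataFrame:
    """Per-transcript feature table: length, GC, counts and densities per preset."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            "transcript_id": r.id,
            "length": r.length,
            "gc_fraction": r.gc_fraction,
        }
        for name, c in r.pg4_counts.items():
            row[f"pg4_count_{name}"] = c
            row[f"pg4_density_{name}"] = r.pg4_density[name]
        if r.biotype is not None:
            row["biotype"] = r.biotype
        rows.append(row)
    return pd.DataFrame(rows).set_index("transcript_id")


def write_bed(hits: Iterable[MotifHit], path) -> None:
    """Write hits as BED6 (0-based half-open; score = number of tracts)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.transcript_id}\t{h.start}\t{h.end}\tpG4\t{len(h.tract_starts)}\t{h.strand}\n"
            )


def read_bed(path) -> list[tuple[str, int, int, str, int, str]]:
    """Read BED6 records written by :func:`write_bed`."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            chrom, start, end, name, score, strand = line.split("\t")
            out.append((chrom, int(start), int(end), name, int(score), strand))
    return out
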