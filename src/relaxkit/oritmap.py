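"""EMSA fragment design, binding-site delineation and repeat scanning for oriT regions.

Overlapping-fragment EMSA maps a protein binding site by testing a ladder of
equal-length DNA fragments offset by a fixed step: the site must lie in the
intersection of all shifted (bound) fragments.  With k consecutive positive
fragments of length L at step d the intersection has length L − (k−1)·d.

Repeat scanning covers the two motif classes relevant to relaxosome assembly:
perfect spacer-free inverted repeats (substrings equal to their own reverse
complement) and same-strand direct repeats of a given motif or k-mer size.

Fragment and scan coordinates are 1-based inclusive; the BED writer converts
to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .errors import ConfigError, InputError
from .seqio import reverse_complement


@dataclass(frozen=True)
class Fragment:
    label: str
    start: int   # 1-based inclusive
    end: int


@dataclass
class FragmentSet:
    """Equal-length fragments tiling a region at a fixed step."""

    region_id: str
    frag_length: int
    step: int
    fragments: list[Fragment]

    def __getitem__(self, label: str) -> Fragment:
        for f in self.fragments:
            if f.label == label:
                return f
        raise KeyError(label)

    def labels(self) -> list[str]:
        return [f.label for f in self.fragments]


@dataclass(frozen=True)
class ShiftCall:
    """Gel-shift outcome for one fragment: none / weak / strong.

    Band intensities are judged by the experimenter; this type only records
    the label, it never thresholds anything.
    """

    label: str
    outcome: str

    def __post_init__(self) -> None:
        if self.outcome not in ("none", "weak", "strong"):
            raise InputError(f"unknown outcome {self.outcome!r}")


def make_fragments(region_length: int, frag_length: int = 200, step: int = 25,
                   first_label: int = 21, region_id: str = "region") -> FragmentSet:
    """Tile a region with F-numbered fragments starting at position 1.

    Fragment count = floor((region_length − frag_length)/step) + 1.
    """
    if step <= 0:
        raise ConfigError("step must be positive")
    if frag_length > region_length:
        raise ConfigError("fragment longer than region")
    frags = []
    start = 1
    i = first_label
    while start + frag_length - 1 <= region_length:
        frags.append(Fragment(f"F{i}", start, start + frag_length - 1))
        start += step
        i += 1
    return FragmentSet(region_id, frag_length, step, frags)


def delineate_site(fragments: FragmentSet, calls: list[ShiftCall],
                   outcome_filter: set[str] = frozenset({"weak", "strong"})
                   ) -> tuple[int, int] | None:
    """Intersection interval of all fragments whose outcome passes the filter.

    Returns a 1-based inclusive (start, end) or ``None`` when no fragment
    passes or the intersection is void.
    """
    chosen = [fragments[c.label] for c in calls if c.outcome in outcome_filter]
    if not chosen:
        return None
    start = max(f.start for f in chosen)
    end = min(f.end for f in chosen)
    return (start, end) if start <= end else None


def interval_length(interval: tuple[int, int] | None) -> int:
    return 0 if interval is None else interval[1] - interval[0] + 1


@dataclass(frozen=True)
class RepeatHit:
    start: int    # 1-based
    length: int
    motif: str


def find_inverted_repeats(seq: str, min_len: int = 6) -> list[RepeatHit]:
    """Maximal perfect spacer-free palindromes (p == revcomp(p)) of length >= min_len.

    Only even lengths exist for spacer-free palindromes.  Maximality is per
    center: a reported palindrome cannot be extended symmetrically by one
    base on each side.
    """
    if min_len % 2 or min_len < 2:
        raise InputError("min_len must be a positive even number")
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    hits = []
    n = len(seq)
    for c in range(n - 1):  # center between c and c+1
        l, r = c, c + 1
        while l >= 0 and r < n and comp.get(seq[l]) == seq[r]:
            l -= 1
            r += 1
        length = r - l - 1
        if length >= min_len:
            hits.append(RepeatHit(l + 2, length, seq[l + 1:r]))
    return hits


def find_direct_repeats(seq: str, motif: str | None = None, k: int | None = None,
                        min_count: int = 2) -> list[RepeatHit] | dict[str, list[int]]:
    """Same-strand repeat scan.

    Motif mode (``motif`` given): all occurrences (overlaps allowed) of the
    motif, as :class:`RepeatHit` entries.  De-novo mode (``k`` given): every
    k-mer occurring >= ``min_count`` times, as {kmer: [positions]}.
    """
    if (motif is None) == (k is None):
        raise InputError("give exactly one of motif or k")
    if motif is not None:
        if set(motif) - set("ACGT"):
            raise InputError("motif must be over ACGT")
        hits = []
        i = seq.find(motif)
        while i != -1:
            hits.append(RepeatHit(i + 1, len(motif), motif))
            i = seq.find(motif, i + 1)
        return hits
    counts: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        counts.setdefault(seq[i:i + k], []).append(i + 1)
    return {m: pos for m, pos in counts.items() if len(pos) >= min_count}


def write_bed(hits: list[RepeatHit], region_id: str, path: str | Path) -> None:
    """Write repeat hits as BED (0-based half-open)."""
    lines = [f"{region_id}\t{h.start - 1}\t{h.start - 1 + h.length}\t{h.motif}"
             for h in hits]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def scan_region(seq: str, motifs: list[str], min_palindrome: int = 6
                ) -> dict[str, object]:
    """Convenience scan: palindromes plus occurrence lists for named motifs."""
    return {
        "inverted_repeats": find_inverted_repeats(seq, min_palindrome),
        "direct_repeats": {m: find_direct_repeats(seq, motif=m) for m in motifs},
    }
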