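"""In-silico tiRNA candidate library generation.

Candidates are built by concatenating k >= 1 non-overlapping substrings
("parts", each >= ``min_part_len`` nt) of the reverse complement of the
target UTR, keeping the order of occurrence of the parts in the reverse
complement.  Total candidate length is drawn from a set of permitted lengths
(default {20, 30, 40} nt).  This mirrors the intuition that effective
antisense riboregulators are largely composed of reverse-complement segments
of their target.

Sampling scheme (uniform-ish coverage of the composition space):

1. draw the total length L uniformly from the permitted lengths;
2. draw the number of parts k uniformly from 1..min(max_parts, L // min_part_len);
3. draw an integer composition of L into k parts, each >= min_part_len,
   uniformly at random;
4. place the parts as ordered non-overlapping intervals of RC(UTR),
   uniformly over all feasible placements (stars-and-bars on the slack).

Duplicates are rejected against a hash set; generation fails with an error
reporting the attained count if the space is exhausted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .fold_engine import RnaSequence, reverse_complement

logger = logging.getLogger("tirnakit")

DEFAULT_LENGTHS = (20, 30, 40)


class LibraryError(RuntimeError):
    """Raised when a candidate library cannot be generated as requested."""


@dataclass
class LibrarySpec:
    """Parameters of the candidate-generation process."""

    target_utr: RnaSequence
    lengths: tuple[int, ...] = DEFAULT_LENGTHS
    n_candidates: int = 1000
    min_part_len: int = 2
    max_parts: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        self.lengths = tuple(sorted(set(int(x) for x in self.lengths)))
        if not self.lengths or min(self.lengths) < 1:
            raise LibraryError("permitted lengths must be positive")
        if self.min_part_len < 2:
            raise LibraryError("min_part_len must be >= 2")
        if self.n_candidates < 1:
            raise LibraryError("n_candidates must be >= 1")
        if len(self.target_utr) < min(self.lengths):
            raise LibraryError(
                "target UTR shorter than the smallest permitted tiRNA length"
            )


def _sample_composition(
    rng: np.random.Generator, total: int, k: int, min_part: int
) -> list[int]:
    """Uniform composition of `total` into k parts each >= min_part."""
    slack = total - k * min_part
    if slack < 0:
        raise ValueError("infeasible composition")
    if k == 1:
        return [total]
    # stars and bars: k-1 cut points among slack + k - 1 slots
    cuts = np.sort(rng.choice(slack + k - 1, size=k - 1, replace=False))
    bars = cuts - np.arange(k - 1)
    parts = np.diff(np.concatenate(([0], bars, [slack])))
    return [int(p) + min_part for p in parts]


def _place_parts(
    rng: np.random.Generator, rc_len: int, part_lens: list[int]
) -> list[tuple[int, int]]:
    """Ordered non-overlapping intervals with the given lengths, uniform over
    all feasible placements (0-based half-open, in RC coordinates)."""
    k = len(part_lens)
    total = sum(part_lens)
    slack = rc_len - total
    if slack < 0:
        raise ValueError("parts do not fit in the reverse complement")
    # distribute slack into k+1 gaps uniformly (stars and bars with k bars)
    if slack == 0:
        gaps = [0] * (k + 1)
    else:
        cuts = np.sort(rng.choice(slack + k, size=k, replace=False))
        bars = cuts - np.arange(k)
        gaps = list(np.diff(np.concatenate(([0], bars, [slack]))))
    intervals = []
    pos = 0
    for g, plen in zip(gaps, part_lens):
        pos += int(g)
        intervals.append((pos, pos + plen))
        pos += plen
    return intervals


def generate_candidate(
    spec: LibrarySpec, rng: np.random.Generator
) -> tuple[RnaSequence, list[tuple[int, int]]]:
    """One candidate plus its part intervals in RC(UTR) coordinates."""
    rc = reverse_complement(spec.target_utr).residues
    feasible_lengths = [L for L in spec.lengths if L <= len(rc)]
    if not feasible_lengths:
        raise LibraryError("target too short for any permitted tiRNA length")
    L = int(rng.choice(feasible_lengths))
    k_max = min(spec.max_parts, L // spec.min_part_len)
    k = int(rng.integers(1, k_max + 1))
    part_lens = _sample_composition(rng, L, k, spec.min_part_len)
    intervals = _place_parts(rng, len(rc), part_lens)
    seq = "".join(rc[a:b] for a, b in intervals)
    return RnaSequence(seq, name="cand"), intervals


def generate_library_full(
    spec: LibrarySpec,
) -> tuple[list[RnaSequence], dict[str, list[tuple[int, int]]]]:
    """Exactly ``spec.n_candidates`` distinct candidates (seeded, duplicates
    rejected) together with per-candidate part intervals in RC coordinates."""
    rng = np.random.default_rng(spec.seed)
    seen: set[str] = set()
    out: list[RnaSequence] = []
    provenance: dict[str, list[tuple[int, int]]] = {}
    max_attempts = 1000 * spec.n_candidates
    attempts = 0
    while len(out) < spec.n_candidates:
        if attempts >= max_attempts:
            raise LibraryError(
                f"candidate space exhausted: {len(out)} unique candidates "
                f"found after {attempts} attempts (requested {spec.n_candidates})"
            )
        attempts += 1
        cand, intervals = generate_candidate(spec, rng)
        if cand.residues in seen:
            continue
        seen.add(cand.residues)
        named = RnaSequence(cand.residues, name=f"tiRNA_{len(out) + 1:05d}")
        out.append(named)
        provenance[named.name] = intervals
    return out, provenance


def generate_library(spec: LibrarySpec) -> list[RnaSequence]:
    """Candidate sequences only; see :func:`generate_library_full`."""
    return generate_library_full(spec)[0]


def provenance_descriptions(
    provenance: dict[str, list[tuple[int, int]]]
) -> dict[str, str]:
    """FASTA description strings: RC-coordinate part intervals, 0-based half-open."""
    return {
        name: "parts_rc=" + ",".join(f"[{a},{b})" for a, b in ivs)
        for name, ivs in provenance.items()
    }


def verify_candidate(
    candidate: RnaSequence,
    target_utr: RnaSequence,
    min_part_len: int = 2,
    max_parts: int | None = None,
) -> bool:
    """Check that the candidate decomposes into >= 1 ordered non-overlapping
    substrings of RC(target), each >= min_part_len nt.

    Dynamic programming over (candidate offset, minimum RC start); greedy
    longest-match would miss valid decompositions.
    """
    rc = reverse_complement(target_utr).residues
    cand = candidate.residues
    n, m = len(cand), len(rc)

    from functools import lru_cache

    @lru_cache(maxsize=None)
    def ok(ci: int, rlo: int, parts_used: int) -> bool:
        if ci == n:
            return parts_used >= 1
        if max_parts is not None and parts_used >= max_parts:
            return False
        for start in range(rlo, m):
            if rc[start] != cand[ci]:
                continue
            # extend the match as far as it goes; any prefix >= min_part_len works
            ext = 0
            while (
                ci + ext < n and start + ext < m and rc[start + ext] == cand[ci + ext]
            ):
                ext += 1
            for plen in range(min_part_len, ext + 1):
                if ok(ci + plen, start + plen, parts_used + 1):
                    return True
        return False

    result = ok(0, 0, 0)
    ok.cache_clear()
    return result


def mean_parts(provenance: dict[str, list[tuple[int, int]]]) -> float:
    """Mean number of parts per candidate in a generated library."""
    counts = [len(v) for v in provenance.values()]
    return float(np.mean(counts))
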