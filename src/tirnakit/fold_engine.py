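"""RNA secondary-structure backends for tiRNA design.

Two engines implement a common contract (fold, cofold, Boltzmann sampling and
accessibility-aware RNA-RNA interaction energetics):

* :class:`BuiltinEngine` — a dependency-free reference engine with a simple
  per-pair energy model (G·C = −3.0, A·U = −2.0, G·U = −1.0 kcal/mol, no
  stacking or loop terms, minimum hairpin loop of 3 nt).  Minimum free energy
  (MFE), the full partition function, base-pair probabilities and stochastic
  backtracking are computed exactly by dynamic programming over nested
  structures, which keeps brute-force enumeration oracles tractable in tests.

* :class:`ViennaEngine` — an adapter over the ViennaRNA Python bindings run
  with options equivalent to ``--noLP -d2``, for users who want a full
  nearest-neighbour thermodynamic model.

Interaction energetics follow the accessibility framework of RNAup: the total
energy of binding a (sub)sequence to a target site is the duplex energy plus
the opening energy of the site, where the opening energy is defined through a
constrained partition function (all pairs touching the site forbidden):

    dG_open(site) = -kT * ln( Z[site unpaired] / Z )  >=  0

Pseudoknots, kinetics and 3D structure are out of scope.
"""

from __future__ import annotations

import logging
import math
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("tirnakit")

# --------------------------------------------------------------------------
# Model constants (built-in engine)
# --------------------------------------------------------------------------

#: per-pair free energies, kcal/mol
PAIR_ENERGIES: dict[frozenset, float] = {
    frozenset("GC"): -3.0,
    frozenset("AU"): -2.0,
    frozenset("GU"): -1.0,
}
#: kT at 37 degC, kcal/mol
KT: float = 0.6163
#: minimum number of unpaired nucleotides in a hairpin loop
MIN_HAIRPIN_LOOP: int = 3
#: default maximal width of an interaction site on the target (nt)
MAX_SITE_WIDTH: int = 25

_VALID = set("ACGU")
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


class FoldingError(RuntimeError):
    """Raised for invalid folding inputs."""


class EngineUnavailableError(FoldingError):
    """Raised when a configured external engine cannot be used."""


# --------------------------------------------------------------------------
# Sequences
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RnaSequence:
    """A validated RNA sequence over {A, C, G, U}.

    DNA-style ``T`` residues are transliterated to ``U`` on ingest with a
    logged warning.  Lower-case input is accepted and upper-cased.
    """

    residues: str
    name: str = "seq"

    def __post_init__(self) -> None:
        res = self.residues.upper()
        if "T" in res:
            logger.warning("sequence %s: transliterating T -> U", self.name)
            res = res.replace("T", "U")
        if len(res) < 1:
            raise ValueError(f"sequence {self.name}: length must be >= 1")
        bad = set(res) - _VALID
        if bad:
            raise ValueError(
                f"sequence {self.name}: invalid residues {sorted(bad)}"
            )
        object.__setattr__(self, "residues", res)

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    def window(self, start: int, stop: int, name: str | None = None) -> "RnaSequence":
        """Return the sub-sequence over the 0-based half-open interval [start, stop)."""
        if not (0 <= start < stop <= len(self.residues)):
            raise ValueError(f"invalid window [{start}, {stop}) for length {len(self)}")
        return RnaSequence(
            self.residues[start:stop],
            name or f"{self.name}[{start}:{stop})",
        )


def reverse_complement(seq: RnaSequence) -> RnaSequence:
    """Reverse complement under A<->U, G<->C."""
    rc = "".join(_COMPLEMENT[c] for c in reversed(seq.residues))
    return RnaSequence(rc, name=f"rc_{seq.name}")


def concat(a: RnaSequence, b: RnaSequence, name: str | None = None) -> RnaSequence:
    return RnaSequence(a.residues + b.residues, name or f"{a.name}+{b.name}")


def read_fasta(path: str | Path) -> list[RnaSequence]:
    """Read RNA sequences from a FASTA file (T transliterated to U)."""
    return [
        RnaSequence(str(rec.seq), name=rec.id)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(
    seqs: Iterable[RnaSequence],
    path: str | Path,
    descriptions: dict[str, str] | None = None,
) -> None:
    recs = [
        SeqRecord(
            Seq(s.residues),
            id=s.name,
            description=(descriptions or {}).get(s.name, ""),
        )
        for s in seqs
    ]
    SeqIO.write(recs, str(path), "fasta")


# --------------------------------------------------------------------------
# Fold results
# --------------------------------------------------------------------------


def pairs_from_dotbracket(structure: str) -> list[tuple[int, int]]:
    """Base pairs (i, j), i < j, of a balanced dot-bracket string."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket: unmatched ')'")
            pairs.append((stack.pop(), i))
        elif c not in ".&":
            raise ValueError(f"invalid dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket: unmatched '('")
    return sorted(pairs)


@dataclass
class MonomerFold:
    """MFE structure, ensemble free energy and pair probabilities of one strand."""

    sequence_length: int
    mfe_structure: str
    mfe_energy: float
    bpp: np.ndarray
    ensemble_energy: float

    @property
    def unpaired_prob(self) -> np.ndarray:
        """Per-nucleotide probability of being unpaired, u_i = 1 - sum_j P(i, j)."""
        return np.clip(1.0 - self.bpp.sum(axis=1), 0.0, 1.0)


@dataclass
class DimerFold:
    """Co-fold of two strands over the concatenation with an explicit nick.

    ``bpp`` is indexed over the n_A + n_B concatenated positions; the
    inter-strand block is ``bpp[:n_A, n_A:]``.  ``mfe_structure`` carries an
    ``&`` separator at the nick (the separator has no matrix position).
    """

    lengths: tuple[int, int]
    mfe_structure: str
    mfe_energy: float
    bpp: np.ndarray
    ensemble_energy: float

    @property
    def inter_bpp(self) -> np.ndarray:
        na, _ = self.lengths
        return self.bpp[:na, na:]


@dataclass
class InteractionResult:
    """RNAup-style site energetics: e_total = e_interaction + opening_energy."""

    e_total: float
    e_interaction: float
    site: tuple[int, int]  # half-open interval on the target; (0, 0) if none
    opening_energy: float


# --------------------------------------------------------------------------
# Built-in engine
# --------------------------------------------------------------------------


class _LRU(OrderedDict):
    def __init__(self, maxsize: int) -> None:
        super().__init__()
        self.maxsize = maxsize

    def put(self, key, value) -> None:
        self[key] = value
        self.move_to_end(key)
        while len(self) > self.maxsize:
            self.popitem(last=False)


class BuiltinEngine:
    """Exact DP engine under the simple per-pair energy model.

    All recursions run over nested (pseudoknot-free) structures with a
    minimum hairpin loop of ``min_loop`` unpaired nucleotides; for a dimer
    the strand nick lifts the loop constraint across the junction and the
    inter-strand initiation penalty is zero by default.
    """

    name = "builtin"

    def __init__(
        self,
        pair_energies: dict | None = None,
        kT: float = KT,
        min_loop: int = MIN_HAIRPIN_LOOP,
        duplex_initiation: float = 0.0,
        max_site_width: int = MAX_SITE_WIDTH,
    ) -> None:
        self.pair_energies = dict(pair_energies or PAIR_ENERGIES)
        self.kT = kT
        self.min_loop = min_loop
        self.duplex_initiation = duplex_initiation
        self.max_site_width = max_site_width
        self._fold_cache: _LRU = _LRU(maxsize=64)
        self._cofold_cache: _LRU = _LRU(maxsize=64)
        self._target_tables: _LRU = _LRU(maxsize=8)
        self._interact_memo: _LRU = _LRU(maxsize=100_000)

    # -- energy model helpers ------------------------------------------------

    def pair_energy(self, a: str, b: str) -> float | None:
        return self.pair_energies.get(frozenset((a, b)))

    def _partners(self, s: str, nick: int | None):
        """Per-position sorted partner indices and energies, honouring the
        minimum-loop rule (lifted across the nick)."""
        n = len(s)
        idx: list[np.ndarray] = []
        en: list[np.ndarray] = []
        for i in range(n):
            ks, es = [], []
            for k in range(i + 1, n):
                e = self.pair_energy(s[i], s[k])
                if e is None:
                    continue
                if (k - i > self.min_loop) or (
                    nick is not None and i < nick <= k
                ):
                    ks.append(k)
                    es.append(e)
            idx.append(np.asarray(ks, dtype=np.intp))
            en.append(np.asarray(es, dtype=float))
        return idx, en

    # -- MFE -----------------------------------------------------------------

    def _mfe_dp(self, s: str, nick: int | None):
        n = len(s)
        p_idx, p_en = self._partners(s, nick)
        E = np.zeros((n + 1, n + 1))
        for d in range(1, n):
            for i in range(n - d):
                j = i + d
                best = E[i + 1, j]
                ks = p_idx[i]
                if ks.size:
                    hi = np.searchsorted(ks, j, side="right")
                    if hi:
                        kk = ks[:hi]
                        cand = p_en[i][:hi] + E[i + 1, kk - 1] + E[kk + 1, j]
                        m = cand.min()
                        if m < best:
                            best = m
                E[i, j] = best
        return E, p_idx, p_en

    def _mfe_structure(self, s: str, nick: int | None, E, p_idx, p_en) -> str:
        """Lexicographically smallest dot-bracket among MFE structures."""
        tol = 1e-9
        memo: dict[tuple[int, int], str] = {}

        def best(i: int, j: int) -> str:
            if i > j:
                return ""
            key = (i, j)
            if key in memo:
                return memo[key]
            opt = E[i, j]
            cands: list[str] = []
            ks = p_idx[i]
            hi = np.searchsorted(ks, j, side="right")
            for t in range(hi):
                k = int(ks[t])
                if abs(p_en[i][t] + E[i + 1, k - 1] + E[k + 1, j] - opt) < tol:
                    cands.append("(" + best(i + 1, k - 1) + ")" + best(k + 1, j))
            if cands:
                res = min(cands)  # '(' < '.', so any pairing beats the dot branch
            else:
                res = "." + best(i + 1, j)
            memo[key] = res
            return res

        return best(0, len(s) - 1)

    # -- partition function / bpp ---------------------------------------------

    def _partition(self, s: str, nick: int | None, mfe: float):
        """Per-nucleotide-scaled partition function Z~(i,j) = Z(i,j) u^(j-i+1)."""
        n = len(s)
        ln_u = mfe / (n * self.kT)  # <= 0; makes the MFE Boltzmann weight ~ 1
        u = math.exp(ln_u)
        p_idx, p_en = self._partners(s, nick)
        w: list[np.ndarray] = [np.exp(-e / self.kT) * u * u for e in p_en]
        Z = np.ones((n + 1, n + 1))
        for i in range(n):
            Z[i, i] = u
        for d in range(1, n):
            for i in range(n - d):
                j = i + d
                z = u * Z[i + 1, j]
                ks = p_idx[i]
                hi = np.searchsorted(ks, j, side="right")
                if hi:
                    kk = ks[:hi]
                    z += float(np.dot(w[i][:hi], Z[i + 1, kk - 1] * Z[kk + 1, j]))
                Z[i, j] = z
        ensemble_energy = -self.kT * (math.log(Z[0, n - 1]) - n * ln_u)
        return Z, u, p_idx, p_en, w, ensemble_energy

    def _bpp_outside(self, s: str, nick: int | None, Z, p_idx, w):
        """McCaskill outside pass; returns (P, WO) with WO(p,q) = w(p,q) O~(p,q)."""
        n = len(s)
        Ztot = Z[0, n - 1]
        P = np.zeros((n, n))
        WO = np.zeros((n, n))
        cells = [
            (i, int(k), float(w[i][t]))
            for i in range(n)
            for t, k in enumerate(p_idx[i])
        ]
        cells.sort(key=lambda c: c[1] - c[0], reverse=True)  # decreasing span
        for i, j, wij in cells:
            t1 = (Z[0, i - 1] if i > 0 else 1.0) * (
                Z[j + 1, n - 1] if j < n - 1 else 1.0
            )
            t2 = 0.0
            if i > 0 and j < n - 1:
                vL = Z[1 : i + 1, i - 1]
                vR = Z[j + 1, j : n - 1]
                t2 = float(vL @ WO[0:i, j + 1 : n] @ vR)
            o = t1 + t2
            WO[i, j] = wij * o
            P[i, j] = wij * Z[i + 1, j - 1] * o / Ztot
        return P + P.T, WO

    # -- public contract -------------------------------------------------------

    def fold(self, seq: RnaSequence) -> MonomerFold:
        cached = self._fold_cache.get(seq.residues)
        if cached is not None:
            return cached
        s = seq.residues
        n = len(s)
        E, p_idx, p_en = self._mfe_dp(s, None)
        mfe = float(E[0, n - 1])
        structure = self._mfe_structure(s, None, E, p_idx, p_en)
        Z, u, p_idx, p_en, w, g_ens = self._partition(s, None, mfe)
        P, _ = self._bpp_outside(s, None, Z, p_idx, w)
        result = MonomerFold(
            sequence_length=n,
            mfe_structure=structure,
            mfe_energy=mfe,
            bpp=P,
            ensemble_energy=g_ens,
        )
        self._fold_cache.put(seq.residues, result)
        return result

    def cofold(self, seq_a: RnaSequence, seq_b: RnaSequence) -> DimerFold:
        """Co-fold two strands.

        Strand order is canonicalised internally (lexicographic by residues)
        so that mfe(A, B) == mfe(B, A) holds exactly; the returned structure
        and bpp blocks are mapped back to the caller's (A, B) order.
        """
        key = (seq_a.residues, seq_b.residues)
        cached = self._cofold_cache.get(key)
        if cached is not None:
            return cached
        swap = seq_b.residues < seq_a.residues
        first, second = (seq_b, seq_a) if swap else (seq_a, seq_b)
        na, nb = len(first), len(second)
        s = first.residues + second.residues
        nick = na
        E, p_idx, p_en = self._mfe_dp(s, nick)
        mfe = float(E[0, len(s) - 1])
        struct = self._mfe_structure(s, nick, E, p_idx, p_en)
        Z, u, p_idx, p_en, w, g_ens = self._partition(s, nick, mfe)
        P, _ = self._bpp_outside(s, nick, Z, p_idx, w)
        if swap:
            # computed on (B, A); B occupies 0..na-1, A occupies na..na+|A|-1.
            # Permute back to (A, B) order.
            perm = np.concatenate([np.arange(na, na + len(seq_a)), np.arange(0, na)])
            P = P[np.ix_(perm, perm)]
            struct = _swap_strand_structure(struct, nick)
        else:
            struct = struct[:nick] + "&" + struct[nick:]
        result = DimerFold(
            lengths=(len(seq_a), len(seq_b)),
            mfe_structure=struct,
            mfe_energy=mfe,
            bpp=P,
            ensemble_energy=g_ens,
        )
        self._cofold_cache.put(key, result)
        return result

    def sample(
        self, seq: RnaSequence, n: int, seed: int, _nick: int | None = None
    ) -> list[str]:
        """Draw n structures i.i.d. from the Boltzmann distribution (seeded)."""
        if n < 1:
            raise ValueError("n must be >= 1")
        s = seq.residues
        length = len(s)
        E, p_idx0, p_en0 = self._mfe_dp(s, _nick)
        mfe = float(E[0, length - 1])
        Z, u, p_idx, p_en, w, _ = self._partition(s, _nick, mfe)
        rng = np.random.default_rng(seed)
        out: list[str] = []
        for _ in range(n):
            chars = ["."] * length
            stack: list[tuple[int, int]] = [(0, length - 1)]
            while stack:
                i, j = stack.pop()
                if i > j:
                    continue
                ztot = Z[i, j]
                r = rng.random() * ztot
                acc = u * Z[i + 1, j]
                if r < acc:
                    stack.append((i + 1, j))
                    continue
                ks = p_idx[i]
                hi = np.searchsorted(ks, j, side="right")
                chosen = None
                for t in range(hi):
                    k = int(ks[t])
                    acc += w[i][t] * Z[i + 1, k - 1] * Z[k + 1, j]
                    if r < acc:
                        chosen = k
                        break
                if chosen is None:  # numerical slack: fall back to last option
                    chosen = int(ks[hi - 1])
                chars[i], chars[chosen] = "(", ")"
                stack.append((i + 1, chosen - 1))
                stack.append((chosen + 1, j))
            out.append("".join(chars))
        return out

    # -- interaction energetics -------------------------------------------------

    def _opening_tables(self, target: RnaSequence):
        """Opening energies dG_open(a, b) for all sites of width <= max_site_width.

        Cached per target.  Uses the constrained-partition-function definition:
        Z with every pair touching [a, b] forbidden, relative to the full Z.
        """
        cached = self._target_tables.get(target.residues)
        if cached is not None:
            return cached
        s = target.residues
        n = len(s)
        E, p_idx, p_en = self._mfe_dp(s, None)
        mfe = float(E[0, n - 1])
        Z, u, p_idx, p_en, w, _ = self._partition(s, None, mfe)
        _, WO = self._bpp_outside(s, None, Z, p_idx, w)
        Ztot = Z[0, n - 1]
        wmax = min(self.max_site_width, n)
        opening = np.full((n, wmax + 1), np.inf)  # [a, width]
        for a in range(n):
            vL = Z[1 : a + 1, a - 1] if a > 0 else None
            for width in range(1, wmax + 1):
                b = a + width - 1
                if b >= n:
                    break
                t1 = (Z[0, a - 1] if a > 0 else 1.0) * (
                    Z[b + 1, n - 1] if b < n - 1 else 1.0
                )
                t2 = 0.0
                if a > 0 and b < n - 1:
                    vR = Z[b + 1, b : n - 1]
                    t2 = float(vL @ WO[0:a, b + 1 : n] @ vR)
                zu = (u ** width) * (t1 + t2)
                opening[a, width] = max(0.0, -self.kT * math.log(zu / Ztot))
        tables = (opening, wmax)
        self._target_tables.put(target.residues, tables)
        return tables

    def _duplex_scan(self, query: str, target: str, wmax: int):
        """Best hybridisation energy H(a, b) for every footprint [a, b] on the
        target (end positions paired), antiparallel, intermolecular pairs only.

        Returns a dict {(a, b): energy}.  Energies are sums of pair energies
        (all <= 0) plus the duplex initiation penalty.
        """
        r = len(query)
        n = len(target)
        e = np.full((r, n), np.inf)
        for i, qc in enumerate(query):
            for j, tc in enumerate(target):
                pe = self.pair_energy(qc, tc)
                if pe is not None:
                    e[i, j] = pe
        H: dict[tuple[int, int], float] = {}
        for b in range(n - 1, -1, -1):
            if not np.isfinite(e[:, b]).any():
                continue
            lo = max(0, b - wmax + 1)
            # M[i] = min over pairs (i', j') already placed with i' <= i, j' > j
            M = np.full(r, np.inf)
            for j in range(b, lo - 1, -1):
                if j == b:
                    D = e[:, b].copy()
                else:
                    pred = np.concatenate(([np.inf], M[:-1]))  # i' < i
                    D = e[:, j] + pred
                col_min = D.min()
                if np.isfinite(col_min):
                    a = j
                    best = H.get((a, b))
                    val = float(col_min) + self.duplex_initiation
                    if best is None or val < best:
                        H[(a, b)] = val
                M = np.minimum(M, np.minimum.accumulate(D))
        return H

    def interact(self, query: RnaSequence, target: RnaSequence) -> InteractionResult:
        """Minimum over target sites of duplex energy + site opening energy."""
        memo_key = (query.residues, target.residues)
        cached = self._interact_memo.get(memo_key)
        if cached is not None:
            return cached
        opening, wmax = self._opening_tables(target)
        H = self._duplex_scan(query.residues, target.residues, wmax)
        best = None
        for (a, b), h in H.items():
            if h >= 0:
                continue
            width = b - a + 1
            if width > wmax:
                continue
            total = h + opening[a, width]
            if best is None or total < best[0]:
                best = (total, h, a, b)
        if best is None or best[0] >= 0:
            result = InteractionResult(0.0, 0.0, (0, 0), 0.0)
        else:
            total, h, a, b = best
            result = InteractionResult(
                e_total=float(total),
                e_interaction=float(h),
                site=(a, b + 1),
                opening_energy=float(total - h),
            )
        self._interact_memo.put(memo_key, result)
        return result


def _swap_strand_structure(struct: str, nick: int) -> str:
    """Rewrite a dot-bracket computed on (B, A) concatenation into (A, B) order.

    Intra-strand pairs keep their orientation; pairs crossing the nick flip
    ('(' on the former second strand becomes ')' on the new first strand).
    """
    pairs = pairs_from_dotbracket(struct)
    n = len(struct)
    na = n - nick  # length of strand A (second block in the computed string)
    mapping = lambda p: p - nick if p >= nick else p + na
    chars = ["."] * n
    for i, j in pairs:
        mi, mj = mapping(i), mapping(j)
        lo, hi = min(mi, mj), max(mi, mj)
        chars[lo], chars[hi] = "(", ")"
    return "".join(chars[:na]) + "&" + "".join(chars[na:])


# --------------------------------------------------------------------------
# ViennaRNA adapter
# --------------------------------------------------------------------------


class ViennaEngine:
    """Adapter over the ViennaRNA Python bindings (``import RNA``).

    Runs with options equivalent to ``--noLP -d2``.  The engine version is
    validated on construction and logged.  Interaction energetics scan target
    windows with ``RNA.duplexfold`` and compute site opening energies from
    hard-constrained partition functions, matching the accessibility
    definition used by the built-in engine.
    """

    name = "viennarna"

    def __init__(self, max_site_width: int = MAX_SITE_WIDTH) -> None:
        try:
            import RNA  # type: ignore
        except ImportError as exc:  # pragma: no cover - environment dependent
            raise EngineUnavailableError(
                "external engine 'viennarna' is configured but the RNA python "
                "bindings are not importable"
            ) from exc
        self._RNA = RNA
        self.max_site_width = max_site_width
        md = RNA.md()
        md.noLP = 1
        md.dangles = 2
        self._md = md
        version = getattr(RNA, "__version__", "unknown")
        logger.info("viennarna engine initialised, version %s", version)
        self.version = version
        self._opening_cache: _LRU = _LRU(maxsize=8)

    def _fc(self, seq: str):
        return self._RNA.fold_compound(seq, self._md)

    def fold(self, seq: RnaSequence) -> MonomerFold:
        RNA = self._RNA
        fc = self._fc(seq.residues)
        structure, mfe = fc.mfe()
        fc.exp_params_rescale(mfe)
        _, g_ens = fc.pf()
        n = len(seq)
        raw = np.array(fc.bpp())[1:, 1:]
        bpp = raw + raw.T
        return MonomerFold(
            sequence_length=n,
            mfe_structure=structure,
            mfe_energy=float(mfe),
            bpp=bpp,
            ensemble_energy=float(g_ens),
        )

    def cofold(self, seq_a: RnaSequence, seq_b: RnaSequence) -> DimerFold:
        fc = self._fc(seq_a.residues + "&" + seq_b.residues)
        structure, mfe = fc.mfe_dimer()
        fc.exp_params_rescale(mfe)
        _, _, _, _, g_ens = fc.pf_dimer()
        na = len(seq_a)
        raw = np.array(fc.bpp())[1:, 1:]
        bpp = raw + raw.T
        struct = structure[:na] + "&" + structure[na:]
        return DimerFold(
            lengths=(na, len(seq_b)),
            mfe_structure=struct,
            mfe_energy=float(mfe),
            bpp=bpp,
            ensemble_energy=float(g_ens),
        )

    def sample(self, seq: RnaSequence, n: int, seed: int) -> list[str]:
        if n < 1:
            raise ValueError("n must be >= 1")
        RNA = self._RNA
        md = RNA.md()
        md.noLP = 1
        md.dangles = 2
        md.uniq_ML = 1  # required for stochastic backtracking
        fc = RNA.fold_compound(seq.residues, md)
        _, mfe = fc.mfe()
        fc.exp_params_rescale(mfe)
        fc.pf()
        RNA.init_rand(int(seed))
        return list(fc.pbacktrack(n))

    def _opening(self, target: RnaSequence, a: int, b: int) -> float:
        """Opening energy of target interval [a, b] (inclusive), cached."""
        cache = self._opening_cache.get(target.residues)
        if cache is None:
            fc = self._fc(target.residues)
            _, mfe = fc.mfe()
            fc.exp_params_rescale(mfe)
            _, g_free = fc.pf()
            cache = {"g_free": float(g_free), "sites": {}, "mfe": mfe}
            self._opening_cache.put(target.residues, cache)
        if (a, b) in cache["sites"]:
            return cache["sites"][(a, b)]
        fc = self._fc(target.residues)
        for pos in range(a, b + 1):
            fc.hc_add_up(pos + 1)  # 1-based; force unpaired
        fc.exp_params_rescale(cache["mfe"])
        _, g_con = fc.pf()
        val = max(0.0, float(g_con) - cache["g_free"])
        cache["sites"][(a, b)] = val
        return val

    def interact(self, query: RnaSequence, target: RnaSequence) -> InteractionResult:
        RNA = self._RNA
        n = len(target)
        wmax = min(self.max_site_width, n)
        best = None
        for a in range(n):
            b_end = min(n, a + wmax)
            window = target.residues[a:b_end]
            dup = RNA.duplexfold(query.residues, window)
            if dup.energy >= 0 or not dup.structure:
                continue
            # dup.j is the 1-based start of the duplex region on the window;
            # the paired footprint is the non-dot span of the target part
            w_struct = dup.structure.split("&")[1]
            paired = [k for k, c in enumerate(w_struct) if c != "."]
            if not paired:
                continue
            t_lo = a + (dup.j - 1) + paired[0]
            t_hi = a + (dup.j - 1) + paired[-1]
            opening = self._opening(target, t_lo, t_hi)
            total = dup.energy + opening
            if best is None or total < best[0]:
                best = (total, float(dup.energy), t_lo, t_hi)
        if best is None or best[0] >= 0:
            return InteractionResult(0.0, 0.0, (0, 0), 0.0)
        total, h, a, b = best
        return InteractionResult(float(total), h, (a, b + 1), float(total - h))

    def verify_reference_fold(
        self, seq: RnaSequence, expected_mfe: float, tol: float = 0.05
    ) -> bool:
        """Check that folding ``seq`` reproduces a printed reference MFE.

        Intended for validating the adapter against published UTR free
        energies when the corresponding sequence is supplied by the user.
        """
        mfe = self.fold(seq).mfe_energy
        ok = abs(mfe - expected_mfe) <= tol
        if not ok:
            logger.warning(
                "reference fold mismatch: got %.2f, expected %.2f", mfe, expected_mfe
            )
        return ok


# --------------------------------------------------------------------------
# Engine selection
# --------------------------------------------------------------------------

_BUILTIN_SINGLETON: BuiltinEngine | None = None


def get_engine(spec: object = "builtin", **options):
    """Resolve an engine selector: an Engine instance, 'builtin' or
    'external'/'viennarna'."""
    global _BUILTIN_SINGLETON
    if hasattr(spec, "fold") and hasattr(spec, "interact"):
        return spec
    if spec in (None, "builtin"):
        if options:
            return BuiltinEngine(**options)
        if _BUILTIN_SINGLETON is None:
            _BUILTIN_SINGLETON = BuiltinEngine()
        return _BUILTIN_SINGLETON
    if spec in ("external", "viennarna", "vienna"):
        return ViennaEngine(**options)
    raise ValueError(f"unknown engine selector {spec!r}")
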