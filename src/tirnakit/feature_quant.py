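"""Quantification of the 12 tiRNA features against a UTR context.

The UTR context is the target 5' UTR extended by the first 50 nt of the
coding sequence.  Features per candidate tiRNA (stable column order):

========  =====================================================================
EA        free energy of the tiRNA monomer (kcal/mol)
EAA       free energy of the tiRNA-tiRNA homodimer (kcal/mol)
EAB       free energy of the tiRNA-UTR dimer (kcal/mol)
FAA       formation energy of the homodimer: EAA - 2*EA
FAB       formation energy of the tiRNA-UTR dimer: EAB - EA - dG_UTR
ETS       mean (over Boltzmann-sampled tiRNA structures) of the minimal total
          energy (duplex + site opening) for binding an unpaired tiRNA
          stretch to the UTR context
EIS       as ETS but the intermolecular duplex energy alone
PAU       availability of the targeted UTR nucleotides: weighted mean of the
          UTR-monomer unpaired probabilities, weighted by the tiRNA-binding
          probabilities from the dimer ensemble
RBS5      mean tiRNA-binding probability over the 5-nt window centred on the
          ribosome-binding-site centre C_RBS
RBS11     as RBS5 with an 11-nt window
PT        mean number of base pairs joining the 5' and 3' halves of the tiRNA
          over Boltzmann-sampled monomer structures
L         tiRNA length (nt)
========  =====================================================================

PAU and the RBS coverages are computed from ensemble base-pair probability
matrices (not single MFE structures).  ETS/EIS/PT average over
``n_samples`` (default 100) structures drawn from the Boltzmann ensemble.
All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fold_engine import (
    RnaSequence,
    concat,
    get_engine,
    pairs_from_dotbracket,
)

logger = logging.getLogger("tirnakit")

FEATURE_COLUMNS = (
    "EA", "EAA", "EAB", "FAA", "FAB", "ETS", "EIS",
    "PAU", "RBS5", "RBS11", "PT", "L",
)

#: default anti-Shine-Dalgarno: reverse complement of the consensus SD
#: AAGGAGGU, with a 1-nt flank (the 16S 3' tail fragment is organism-specific
#: and config-overridable)
DEFAULT_ANTI_SD = "ACCUCCUUA"

DEFAULT_N_SAMPLES = 100
DEFAULT_MIN_RUN = 3


class RbsCenterError(RuntimeError):
    """Raised when the anti-SD shows no binding to the context; the user must
    then supply c_rbs explicitly."""


@dataclass
class UtrContext:
    """Folding context for feature computation: UTR + first 50 nt of CDS."""

    utr: RnaSequence
    cds_prefix: RnaSequence
    combined: RnaSequence
    monomer_fold: object  # MonomerFold, cached
    anti_sd: RnaSequence
    c_rbs: int

    @classmethod
    def build(
        cls,
        utr: RnaSequence,
        cds_prefix: RnaSequence,
        engine="builtin",
        anti_sd: str | RnaSequence = DEFAULT_ANTI_SD,
        c_rbs: int | None = None,
    ) -> "UtrContext":
        eng = get_engine(engine)
        combined = concat(utr, cds_prefix, name=f"{utr.name}+cds")
        if isinstance(anti_sd, str):
            anti_sd = RnaSequence(anti_sd, name="anti_sd")
        fold = eng.fold(combined)
        if c_rbs is None:
            c_rbs = rbs_center(combined, anti_sd, eng)
        if not (0 <= c_rbs < len(combined)):
            raise ValueError("c_rbs outside the combined context")
        return cls(
            utr=utr,
            cds_prefix=cds_prefix,
            combined=combined,
            monomer_fold=fold,
            anti_sd=anti_sd,
            c_rbs=c_rbs,
        )


# --------------------------------------------------------------------------
# individual features
# --------------------------------------------------------------------------


def thermo_features(tirna: RnaSequence, ctx: UtrContext, engine="builtin"):
    """(EA, EAA, EAB, FAA, FAB) from monomer/dimer free energies."""
    eng = get_engine(engine)
    ea = eng.fold(tirna).mfe_energy
    eaa = eng.cofold(tirna, tirna).mfe_energy
    eab = eng.cofold(tirna, ctx.combined).mfe_energy
    dg_utr = ctx.monomer_fold.mfe_energy
    faa = eaa - 2.0 * ea
    fab = eab - ea - dg_utr
    return ea, eaa, eab, faa, fab


def _unpaired_runs(structure: str, min_run: int) -> list[tuple[int, int]]:
    """Maximal runs of unpaired positions of length >= min_run (half-open)."""
    runs = []
    start = None
    for i, c in enumerate(structure + ")"):  # sentinel terminates a final run
        if c == ".":
            if start is None:
                start = i
        else:
            if start is not None and i - start >= min_run:
                runs.append((start, i))
            start = None
    return runs


def seed_energies(
    tirna: RnaSequence,
    ctx: UtrContext,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    engine="builtin",
    min_run: int = DEFAULT_MIN_RUN,
) -> tuple[float, float]:
    """(ETS, EIS): mean minimal total / interaction energy of binding unpaired
    tiRNA stretches to the UTR context, over Boltzmann-sampled structures."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    eng = get_engine(engine)
    structures = Counter(eng.sample(tirna, n_samples, seed))
    ets_sum = eis_sum = 0.0
    no_run_count = 0
    for structure, mult in structures.items():
        runs = _unpaired_runs(structure, min_run)
        if not runs:
            no_run_count += mult
            continue  # contributes 0 to both sums
        best_total = 0.0
        best_inter = 0.0
        for a, b in runs:
            res = eng.interact(tirna.window(a, b), ctx.combined)
            best_total = min(best_total, res.e_total)
            best_inter = min(best_inter, res.e_interaction)
        ets_sum += mult * best_total
        eis_sum += mult * best_inter
    if no_run_count:
        logger.debug(
            "%s: %d/%d sampled structures had no unpaired run >= %d nt",
            tirna.name, no_run_count, n_samples, min_run,
        )
    return ets_sum / n_samples, eis_sum / n_samples


def _binding_weights(tirna: RnaSequence, ctx: UtrContext, eng) -> np.ndarray:
    """w_i: probability that context position i is bound by the tiRNA in the
    tiRNA-context dimer ensemble (sum of inter-strand bpp over tiRNA
    positions)."""
    dimer = eng.cofold(tirna, ctx.combined)
    return dimer.inter_bpp.sum(axis=0)


def pau(tirna: RnaSequence, ctx: UtrContext, engine="builtin") -> float:
    """Availability of the targeted nucleotides: sum_i w_i u_i / sum_i w_i."""
    eng = get_engine(engine)
    w = _binding_weights(tirna, ctx, eng)
    wsum = float(w.sum())
    if wsum <= 0.0:
        logger.warning("%s binds nowhere on the context; PAU set to 0", tirna.name)
        return 0.0
    u = ctx.monomer_fold.unpaired_prob
    return float(np.dot(w, u) / wsum)


def rbs_center(combined: RnaSequence, anti_sd: RnaSequence, engine="builtin") -> int:
    """C_RBS: weighted mean position of the context nucleotides bound by the
    anti-SD (16S rRNA tail fragment) in the anti-SD/context dimer ensemble.

    Rounded to the nearest integer, ties toward the CDS (larger index).
    """
    eng = get_engine(engine)
    dimer = eng.cofold(anti_sd, combined)
    b = dimer.inter_bpp.sum(axis=0)
    bsum = float(b.sum())
    if bsum <= 0.0:
        raise RbsCenterError(
            "anti-SD sequence shows no binding to the UTR context; "
            "supply c_rbs explicitly"
        )
    center = float(np.dot(np.arange(len(b)), b) / bsum)
    return int(np.floor(center + 0.5))


def rbs_coverage(
    tirna: RnaSequence, ctx: UtrContext, width: int, engine="builtin"
) -> float:
    """Mean tiRNA-binding probability over the width-5 or width-11 window
    centred on C_RBS (window truncated at the context ends)."""
    if width not in (5, 11):
        raise ValueError("width must be 5 or 11")
    eng = get_engine(engine)
    h = width // 2
    n = len(ctx.combined)
    lo = max(0, ctx.c_rbs - h)
    hi = min(n, ctx.c_rbs + h + 1)
    w = _binding_weights(tirna, ctx, eng)
    return float(w[lo:hi].mean())


def paired_termini(
    tirna: RnaSequence,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    engine="builtin",
) -> float:
    """Mean number of base pairs joining positions [0, L//2) to [L//2, L)
    over Boltzmann-sampled monomer structures (a pair is one binding event)."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    eng = get_engine(engine)
    half = len(tirna) // 2
    total = 0
    for structure, mult in Counter(eng.sample(tirna, n_samples, seed)).items():
        cross = sum(1 for i, j in pairs_from_dotbracket(structure) if i < half <= j)
        total += mult * cross
    return total / n_samples


# --------------------------------------------------------------------------
# feature vector / table
# --------------------------------------------------------------------------


def derive_seed(master_seed: int, index: int) -> int:
    """Stable per-candidate seed below 2**31."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def feature_vector(
    tirna: RnaSequence,
    ctx: UtrContext,
    seed: int = 0,
    engine="builtin",
    n_samples: int = DEFAULT_N_SAMPLES,
    min_run: int = DEFAULT_MIN_RUN,
) -> dict[str, float]:
    """All 12 features of one candidate, as an ordered dict."""
    eng = get_engine(engine)
    ea, eaa, eab, faa, fab = thermo_features(tirna, ctx, eng)
    ets, eis = seed_energies(
        tirna, ctx, n_samples=n_samples, seed=seed, engine=eng, min_run=min_run
    )
    p_au = pau(tirna, ctx, eng)
    r5 = rbs_coverage(tirna, ctx, 5, eng)
    r11 = rbs_coverage(tirna, ctx, 11, eng)
    pt = paired_termini(tirna, n_samples=n_samples, seed=seed, engine=eng)
    return {
        "EA": ea, "EAA": eaa, "EAB": eab, "FAA": faa, "FAB": fab,
        "ETS": ets, "EIS": eis, "PAU": p_au, "RBS5": r5, "RBS11": r11,
        "PT": pt, "L": float(len(tirna)),
    }


def feature_table(
    candidates: list[RnaSequence],
    ctx: UtrContext,
    seed: int = 0,
    engine="builtin",
    n_samples: int = DEFAULT_N_SAMPLES,
    min_run: int = DEFAULT_MIN_RUN,
) -> pd.DataFrame:
    """Candidate x 12-feature table.

    Per-candidate seeds are derived from (seed, candidate index) so that the
    table is reproducible independently of evaluation order.  Per-candidate
    failures become all-NaN rows with the reason recorded in
    ``table.attrs['failures']`` — never silent drops.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    eng = get_engine(engine)
    rows = []
    failures: dict[str, str] = {}
    for idx, cand in enumerate(candidates):
        child_seed = derive_seed(seed, idx)
        try:
            rows.append(
                feature_vector(
                    cand, ctx, seed=child_seed, engine=eng,
                    n_samples=n_samples, min_run=min_run,
                )
            )
        except Exception as exc:  # noqa: BLE001 - recorded, not dropped
            logger.error("feature computation failed for %s: %s", cand.name, exc)
            failures[cand.name] = str(exc)
            rows.append({c: np.nan for c in FEATURE_COLUMNS})
    table = pd.DataFrame(rows, index=[c.name for c in candidates])
    table = table[list(FEATURE_COLUMNS)]
    table.index.name = "candidate"
    table.attrs["failures"] = failures
    return table


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", float_format="%.10g")


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="candidate")
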