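"""Deterministic synthetic inputs for every pipeline stage.

Nothing here models translation mechanistically; the generators produce
structurally plausible toy inputs with known ground truth so that folding,
feature quantification, design selection, plate normalisation and the
regression models can be exercised end-to-end offline:

* toy target UTRs with an embedded consensus Shine-Dalgarno site upstream
  of an AUG-initiated CDS prefix;
* simulated relative-expression responses from a log-linear model with a
  known coefficient vector (the single-feature case coincides with the
  log-linear OLS model, so noiseless responses are exactly recoverable);
* plate-reader tables (FP/OD wells with blanks and no-FP controls) whose
  normalisation recovers prescribed expression truths;
* a latent-factor regression problem with a known number of latent
  directions, for PLS dimension-recovery studies.

Child seeds for the pipeline stages are fanned out from a master seed by
stable hashing, so stages are individually reproducible.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fold_engine import RnaSequence

logger = logging.getLogger("tirnakit")

SD_MOTIF = "AGGAGG"
SD_SPACER = 7  # nt between the SD motif and the start codon
CDS_PREFIX_LEN = 50


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable child seed (< 2**31) for a named pipeline stage."""
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class SimSpec:
    utr_length: int = 60
    gc_fraction: float = 0.5
    sd_site: bool = True
    coefficients: dict[str, float] = field(default_factory=dict)
    intercept: float = 1.5  # log10 percent; 10**1.5 ~ 32% baseline
    noise_sd: float = 0.1  # on the log10 scale
    n_observations: int = 36
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError("gc_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def _random_rna(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGU"), size=n, p=probs))


def make_toy_utr(spec: SimSpec) -> tuple[RnaSequence, RnaSequence]:
    """(utr, cds_prefix): random UTR with, when requested, one consensus SD
    motif ending ``SD_SPACER`` nt upstream of the AUG of a 50-nt CDS prefix."""
    if spec.utr_length < 20:
        raise ValueError("utr_length must be >= 20")
    rng = np.random.default_rng(spec.seed)
    for _ in range(1000):
        utr = _random_rna(rng, spec.utr_length, spec.gc_fraction)
        cds = "AUG" + _random_rna(rng, CDS_PREFIX_LEN - 3, spec.gc_fraction)
        if spec.sd_site:
            pos = spec.utr_length - SD_SPACER - len(SD_MOTIF)
            if pos < 0:
                raise ValueError("utr too short to host an SD site")
            utr = utr[:pos] + SD_MOTIF + utr[pos + len(SD_MOTIF) :]
            if (utr + cds).count(SD_MOTIF) != 1:
                continue  # resample: motif must occur exactly once
        return (
            RnaSequence(utr, name="toy_utr"),
            RnaSequence(cds, name="toy_cds_prefix"),
        )
    raise RuntimeError("could not place a unique SD motif; adjust spec")


def simulate_responses(features: pd.DataFrame, spec: SimSpec) -> pd.Series:
    """Relative protein expression (%) from a log-linear model:
    y = 10**(b0 + sum_m b_m x_m + eps), eps ~ N(0, noise_sd), clipped to
    (0, 100]."""
    unknown = set(spec.coefficients) - set(features.columns)
    if unknown:
        raise ValueError(f"coefficients reference unknown features {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed)
    log10y = np.full(len(features), spec.intercept, dtype=float)
    for name, beta in spec.coefficients.items():
        log10y += beta * features[name].to_numpy(dtype=float)
    if spec.noise_sd > 0:
        log10y += rng.normal(0.0, spec.noise_sd, size=len(features))
    y = np.minimum(10.0**log10y, 100.0)
    return pd.Series(y, index=features.index, name="relative_expression")


def make_plate_table(
    expression_truths: dict[str, float],
    n_replicates: int = 3,
    seed: int = 0,
    reference_fpod: float = 2000.0,
    fp_bg: float = 100.0,
    od_bg: float = 0.1,
    od_culture: float = 0.6,
    noise_cv: float = 0.0,
) -> pd.DataFrame:
    """Long-format plate table (strain, well, FP, OD, role).

    ``expression_truths`` maps strain name -> relative expression (%),
    including a ``reference`` strain at 100%.  With ``noise_cv`` = 0 the
    normalisation pipeline recovers the truths exactly; otherwise wells get
    multiplicative lognormal replicate noise on FP.
    """
    rng = np.random.default_rng(seed)
    rows = []
    well = 0
    for rep in range(n_replicates):
        rows.append(
            {"strain": "blank", "well": f"W{well}", "FP": fp_bg * 0.5,
             "OD": od_bg, "role": "medium_blank"}
        )
        well += 1
        rows.append(
            {"strain": "no_fp", "well": f"W{well}", "FP": fp_bg,
             "OD": od_culture, "role": "no_fp_control"}
        )
        well += 1
    for strain, truth in expression_truths.items():
        fpod = reference_fpod * truth / 100.0
        for rep in range(n_replicates):
            noise = (
                rng.lognormal(mean=0.0, sigma=noise_cv) if noise_cv > 0 else 1.0
            )
            fp = fp_bg + fpod * (od_culture - od_bg) * noise
            rows.append(
                {"strain": strain, "well": f"W{well}", "FP": fp,
                 "OD": od_culture, "role": "sample"}
            )
            well += 1
    return pd.DataFrame(rows)


def simulate_latent_problem(
    n: int = 30,
    k: int = 12,
    n_latent: int = 4,
    latent_scales: tuple[float, ...] = (5.0, 4.0, 3.0, 2.0),
    x_noise_sd: float = 0.0,
    y_noise_sd: float = 0.15,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) with a known latent dimension for PLS recovery studies.

    X = T L' + E with orthonormal loadings L (k x n_latent), latent scores T
    scaled by ``latent_scales``, and optional isotropic residual noise E
    (zero by default, making X exactly rank ``n_latent``); the response
    loads on every latent direction, y = T c + eps.  With the defaults the
    recoverable dimension is unambiguously ``n_latent``: no further
    components exist in X, and each latent direction carries a y signal
    well above the response noise.
    """
    if len(latent_scales) != n_latent:
        raise ValueError("need one scale per latent direction")
    rng = np.random.default_rng(seed)
    loadings, _ = np.linalg.qr(rng.normal(size=(k, n_latent)))
    scores = rng.normal(size=(n, n_latent)) * np.asarray(latent_scales)
    X = scores @ loadings.T + rng.normal(scale=x_noise_sd, size=(n, k))
    c = np.asarray([1.0, -0.9, 0.8, -0.7][:n_latent])
    y = scores @ c + rng.normal(scale=y_noise_sd, size=n)
    return X, y
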