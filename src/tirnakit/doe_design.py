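"""Fractional-factorial design generation, feature scaling and candidate
matching.

The default design is the regular 2^(6-2) resolution-IV fraction with
generator words E = ABC and F = BCD (the standard minimum-aberration
choice), giving 16 factorial runs, plus 2 all-zero center points: 18 runs.
Its defining relation is I = ABCE = BCDF = ADEF; the shortest word has
length 4, so main effects are aliased only with three-factor (and higher)
interactions.

Raw library features are mapped to coded units by centring/scaling on the
0.1 and 0.9 quantiles of the library distribution:

    x~ = (x - (q0.9 + q0.1)/2) / ((q0.9 - q0.1)/2)

after multiplying FAB and EIS by -1 (sign convention so that stronger
repression corresponds to larger coded values / positive regression
coefficients).  Values outside [-1, 1] are permitted (library tails).

Design points cannot be dialled in directly — a candidate's features are a
consequence of its sequence — so candidates are matched to design rows by
the residual sum of squares (RSS) between the coded design point and the
candidate's scaled feature vector, either greedily in run order (default,
without replacement) or by a globally optimal assignment.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger("tirnakit")

DEFAULT_GENERATORS = {"E": "ABC", "F": "BCD"}
DEFAULT_SIGNS = {"FAB": -1.0, "EIS": -1.0}


class DesignError(ValueError):
    pass


# --------------------------------------------------------------------------
# design generation
# --------------------------------------------------------------------------


def _word_group(n_base: int, generators: dict[str, str]) -> list[frozenset]:
    """Defining-relation group (as letter sets) of a regular 2-level fraction.

    Each generator 'E = ABC' contributes the word ABCE; the group is closed
    under symmetric difference (mod-2 multiplication of effect words).
    """
    base_letters = [chr(ord("A") + i) for i in range(n_base)]
    words = []
    for gen_letter, word in generators.items():
        letters = set(word)
        unknown = letters - set(base_letters) - set(generators)
        if unknown:
            raise DesignError(f"generator {gen_letter}={word}: unknown letters {unknown}")
        words.append(frozenset(letters | {gen_letter}))
    group: set[frozenset] = {frozenset()}
    for w in words:
        group |= {g ^ w for g in group}
    return sorted(group, key=lambda g: (len(g), sorted(g)))


@dataclass
class DesignMatrix:
    factors: list[str]
    runs: np.ndarray  # (n_runs, n_factors) coded in {-1, 0, +1}
    generators: dict[str, str]
    resolution: int
    n_center: int
    defining_relation: list[str]
    aliases: dict[str, list[str]]

    @property
    def n_factorial(self) -> int:
        return int((np.abs(self.runs).sum(axis=1) > 0).sum())

    def to_frame(self) -> pd.DataFrame:
        idx = [f"run{i + 1:02d}" for i in range(self.runs.shape[0])]
        return pd.DataFrame(self.runs, columns=self.factors, index=idx)

    def to_json(self, path=None) -> str:
        payload = {
            "factors": self.factors,
            "generators": self.generators,
            "resolution": self.resolution,
            "n_center": self.n_center,
            "defining_relation": self.defining_relation,
            "aliases": self.aliases,
            "runs": self.runs.tolist(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def generate_design(
    n_factors: int = 6,
    fraction_exponent: int = 2,
    n_center: int = 2,
    generators: dict[str, str] | None = None,
    factor_names: list[str] | None = None,
    min_resolution: int = 4,
) -> DesignMatrix:
    """Regular 2^(n_factors - fraction_exponent) design plus center points."""
    generators = dict(DEFAULT_GENERATORS if generators is None else generators)
    n_base = n_factors - fraction_exponent
    if len(generators) != fraction_exponent:
        raise DesignError("need one generator per fractioned factor")
    letters = [chr(ord("A") + i) for i in range(n_base)] + sorted(generators)
    group = _word_group(n_base, generators)
    nontrivial = [g for g in group if g]
    # a full factorial (no generators) has no defining words: no aliasing
    resolution = min((len(g) for g in nontrivial), default=n_factors + 1)
    if resolution < min_resolution:
        offender = min(nontrivial, key=len)
        raise DesignError(
            f"generators give resolution {resolution} < {min_resolution}: "
            f"short word {''.join(sorted(offender))}"
        )
    # factorial runs: full factorial on base letters (first letter fastest),
    # generated columns as products of their defining base columns
    base_runs = np.array(
        [list(levels) for levels in itertools.product([-1, 1], repeat=n_base)]
    )[:, ::-1]
    cols = {letters[i]: base_runs[:, i] for i in range(n_base)}
    for gen_letter in sorted(generators):
        word = generators[gen_letter]
        col = np.ones(base_runs.shape[0], dtype=int)
        for c in word:
            col = col * cols[c]
        cols[gen_letter] = col
    factorial = np.column_stack([cols[let] for let in letters])
    runs = np.vstack([factorial, np.zeros((n_center, n_factors), dtype=int)])
    # alias structure of main effects (words up to the full defining relation)
    aliases: dict[str, list[str]] = {}
    for let in letters:
        al = []
        for g in nontrivial:
            eff = frozenset({let}) ^ g
            al.append("".join(sorted(eff)))
        aliases[let] = sorted(al, key=lambda s: (len(s), s))
    names = list(factor_names) if factor_names else letters
    if len(names) != n_factors:
        raise DesignError("factor_names length must equal n_factors")
    return DesignMatrix(
        factors=names,
        runs=runs,
        generators=generators,
        resolution=resolution,
        n_center=n_center,
        defining_relation=["I"] + ["".join(sorted(g)) for g in nontrivial],
        aliases={names[letters.index(k)]: v for k, v in aliases.items()},
    )


# --------------------------------------------------------------------------
# quantile scaling
# --------------------------------------------------------------------------


@dataclass
class ScalingAnchors:
    """Per-feature 0.1/0.9 quantile anchors and sign conventions.

    Quantiles use linear interpolation between order statistics ("type 7").
    The sign is applied *before* quantile centring, so anchors are quoted on
    the sign-flipped scale.
    """

    q_low: pd.Series
    q_high: pd.Series
    signs: pd.Series

    @classmethod
    def from_library(
        cls,
        table: pd.DataFrame,
        features: list[str] | None = None,
        signs: dict[str, float] | None = None,
        p_low: float = 0.1,
        p_high: float = 0.9,
    ) -> "ScalingAnchors":
        feats = list(features) if features else list(table.columns)
        signs = dict(DEFAULT_SIGNS if signs is None else signs)
        sgn = pd.Series({f: signs.get(f, 1.0) for f in feats})
        flipped = table[feats] * sgn
        q_low = flipped.quantile(p_low, interpolation="linear")
        q_high = flipped.quantile(p_high, interpolation="linear")
        degenerate = [f for f in feats if q_high[f] <= q_low[f]]
        if degenerate:
            raise DesignError(
                f"degenerate feature(s) {degenerate}: 0.1 and 0.9 quantiles coincide"
            )
        return cls(q_low=q_low, q_high=q_high, signs=sgn)

    def to_json(self, path=None) -> str:
        payload = {
            "quantile_rule": "type 7 (linear interpolation)",
            "q_low": self.q_low.round(12).to_dict(),
            "q_high": self.q_high.round(12).to_dict(),
            "signs": self.signs.to_dict(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def scale_feature(x, anchors: ScalingAnchors, feature: str):
    """Coded value of a raw feature measurement (may fall outside [-1, 1])."""
    lo, hi = anchors.q_low[feature], anchors.q_high[feature]
    xs = anchors.signs[feature] * x
    return (xs - (hi + lo) / 2.0) / ((hi - lo) / 2.0)


def unscale_feature(z, anchors: ScalingAnchors, feature: str):
    lo, hi = anchors.q_low[feature], anchors.q_high[feature]
    return anchors.signs[feature] * (z * (hi - lo) / 2.0 + (hi + lo) / 2.0)


def scale_table(table: pd.DataFrame, anchors: ScalingAnchors) -> pd.DataFrame:
    feats = list(anchors.q_low.index)
    out = pd.DataFrame(
        {f: scale_feature(table[f], anchors, f) for f in feats},
        index=table.index,
    )
    return out


# --------------------------------------------------------------------------
# candidate matching
# --------------------------------------------------------------------------


@dataclass
class SelectionResult:
    assignments: pd.DataFrame  # run, candidate, rss + scaled feature columns
    mean_rss: float
    mode: str

    def to_frame(self) -> pd.DataFrame:
        return self.assignments


def match_candidates(
    design: DesignMatrix,
    scaled_library: pd.DataFrame,
    optimal: bool = False,
) -> SelectionResult:
    """Assign one library candidate to each design run, minimising the RSS
    between coded design levels and scaled features.

    Default: greedy without replacement in run order.  ``optimal=True``
    solves the global minimum-total-RSS assignment instead.
    """
    feats = design.factors
    missing = [f for f in feats if f not in scaled_library.columns]
    if missing:
        raise DesignError(f"scaled library lacks design factors {missing}")
    lib = scaled_library[feats].dropna()
    n_runs = design.runs.shape[0]
    if len(lib) < n_runs:
        raise DesignError(
            f"library has {len(lib)} candidates but the design needs {n_runs}"
        )
    X = lib.to_numpy(dtype=float)
    D = design.runs.astype(float)
    # rss[r, c] = sum over factors of (design level - scaled feature)^2
    rss = ((D[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    chosen_idx = np.empty(n_runs, dtype=int)
    if optimal:
        rows, cols = linear_sum_assignment(rss)
        chosen_idx[rows] = cols
        mode = "optimal"
    else:
        used = np.zeros(len(lib), dtype=bool)
        for r in range(n_runs):
            masked = np.where(used, np.inf, rss[r])
            c = int(np.argmin(masked))
            chosen_idx[r] = c
            used[c] = True
        mode = "greedy"
    records = []
    for r in range(n_runs):
        c = chosen_idx[r]
        rec = {
            "run": f"run{r + 1:02d}",
            "candidate": lib.index[c],
            "rss": float(rss[r, c]),
        }
        rec.update({f: float(X[c, k]) for k, f in enumerate(feats)})
        records.append(rec)
    frame = pd.DataFrame(records).set_index("run")
    return SelectionResult(
        assignments=frame, mean_rss=float(frame["rss"].mean()), mode=mode
    )
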