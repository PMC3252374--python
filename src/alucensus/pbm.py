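"""Binder calling from replicate protein-binding-microarray scores.

Each probe is printed on the array several times (4 spots per grid, 4
grids in the reference design); its final score is the unweighted mean over
all spots of all grids. The binder threshold is derived from the random
negative-control probes: mean + ``multiplier`` x sample SD (n-1 denominator)
of the control mean scores, with strict ``>`` at the boundary. Empirical
p-values are computed against the control score distribution with an
add-one correction; a parametric (normal-tail) alternative is provided as
well. Position weight matrices are built from the set of bound sequences by
straight per-position base frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


def aggregate_replicates(score_table: pd.DataFrame) -> pd.Series:
    """Mean score per probe over all replicate spot columns.

    ``score_table`` has one row per probe with columns ``id``, ``category``,
    ``sequence`` and one column per spot (any column whose name starts with
    ``score``). Missing spots (NaN) are ignored; a probe with no valid spot
    raises.
    """
    score_cols = [c for c in score_table.columns if c.startswith("score")]
    if not score_cols:
        raise ValueError("score table has no score columns")
    values = score_table[score_cols]
    n_valid = values.notna().sum(axis=1)
    if (n_valid == 0).any():
        bad = score_table.loc[n_valid == 0, "id"].tolist()
        raise ValueError(f"probes with zero valid spots: {bad}")
    means = values.mean(axis=1, skipna=True)
    means.index = score_table["id"].values
    return means


@dataclass(frozen=True)
class BinderThreshold:
    """Control-derived binder score cutoff: mean + multiplier * sample SD."""

    control_mean: float
    control_sd: float
    multiplier: float = 2.0

    @property
    def threshold(self) -> float:
        return self.control_mean + self.multiplier * self.control_sd


def compute_threshold(control_scores: Sequence[float], multiplier: float = 2.0) -> BinderThreshold:
    scores = np.asarray(list(control_scores), dtype=float)
    if scores.size < 2:
        raise ValueError("need at least 2 control scores to estimate an SD")
    return BinderThreshold(float(scores.mean()), float(scores.std(ddof=1)), multiplier)


@dataclass(frozen=True)
class BindingCall:
    probe_id: str
    mean_score: float
    is_binder: bool
    empirical_p: float


def call_binders(mean_scores: Mapping[str, float] | pd.Series,
                 threshold: BinderThreshold,
                 control_scores: Sequence[float]) -> List[BindingCall]:
    """Classify probes as binders (strictly above threshold) with p-values.

    ``empirical_p`` for a score s is (#controls >= s + 1) / (#controls + 1):
    the add-one form never returns 0 and equals 1/(n+1) for a score above
    every control.
    """
    controls = np.sort(np.asarray(list(control_scores), dtype=float))
    n = controls.size
    items = mean_scores.items() if hasattr(mean_scores, "items") else mean_scores
    calls = []
    for probe_id, score in items:
        n_ge = n - np.searchsorted(controls, score, side="left")
        calls.append(BindingCall(
            probe_id=probe_id,
            mean_score=float(score),
            is_binder=bool(score > threshold.threshold),
            empirical_p=float((n_ge + 1) / (n + 1)),
        ))
    return calls


def normal_pvalues(mean_scores: Mapping[str, float] | pd.Series,
                   threshold: BinderThreshold) -> Dict[str, float]:
    """Parametric upper-tail p-values under Normal(control_mean, control_sd)."""
    items = mean_scores.items() if hasattr(mean_scores, "items") else mean_scores
    mu, sd = threshold.control_mean, threshold.control_sd
    out = {}
    for probe_id, score in items:
        if sd == 0:
            out[probe_id] = 0.0 if score > mu else 1.0
        else:
            out[probe_id] = 0.5 * math.erfc((score - mu) / (sd * math.sqrt(2.0)))
    return out


def calls_to_frame(calls: Iterable[BindingCall],
                   sequences: Optional[Mapping[str, str]] = None) -> pd.DataFrame:
    rows = [(c.probe_id,
             sequences.get(c.probe_id, "") if sequences else "",
             c.mean_score, c.is_binder, c.empirical_p) for c in calls]
    return pd.DataFrame(rows, columns=["id", "sequence", "mean_score", "is_binder", "empirical_p"])


@dataclass
class PWM:
    """Position weight matrix of per-position base frequencies.

    ``freq`` is an (L, 4) array in A, C, G, T order; each row sums to 1.
    ``info_content`` is per-position information in bits,
    2 + sum_b f log2 f with 0*log 0 = 0, hence in [0, 2].
    """

    length: int
    freq: np.ndarray
    counts: int
    info_content: np.ndarray


def build_pwm(bound_sequences: Sequence[str], pseudocount: float = 0.0) -> PWM:
    """Per-position base frequencies of an equal-length bound sequence set."""
    seqs = list(bound_sequences)
    if not seqs:
        raise ValueError("empty sequence set")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences must all have the same length; "
                         "build separate matrices per length")
    counts = np.full((length, 4), pseudocount, dtype=float)
    for seq in seqs:
        for pos, base in enumerate(seq.upper()):
            try:
                counts[pos, _BASE_INDEX[base]] += 1
            except KeyError:
                raise ValueError(f"non-ACGT base {base!r} in {seq!r}") from None
    freq = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    info = 2.0 + plogp.sum(axis=1)
    return PWM(length=length, freq=freq, counts=len(seqs), info_content=info)


def pwm_to_text(pwm: PWM) -> str:
    """Plain-text matrix: 4 rows (A/C/G/T) x L columns of frequencies."""
    lines = []
    for i, base in enumerate(_BASES):
        lines.append(base + "\t" + "\t".join(f"{v:.6f}" for v in pwm.freq[:, i]))
    return "\n".join(lines) + "\n"


def pwm_to_meme(pwm: PWM, name: str = "motif") -> str:
    """MEME minimal motif format block."""
    lines = [
        "MEME version 4", "",
        "ALPHABET= ACGT", "",
        "strands: + -", "",
        "Background letter frequencies",
        "A 0.25 C 0.25 G 0.25 T 0.25", "",
        f"MOTIF {name}",
        f"letter-probability matrix: alength= 4 w= {pwm.length} nsites= {pwm.counts}",
    ]
    for row in pwm.freq:
        lines.append(" ".join(f"{v:.6f}" for v in row))
    return "\n".join(lines) + "\n"
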