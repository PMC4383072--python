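"""Empirical rEHH significance: 20 x 5% frequency bins, within-bin log transform,
normal upper-tail p-values, and the >25%-frequency reporting rule.

The empirical distribution is fitted on ALL core alleles (any frequency); the
frequency rule only restricts which alleles are reported and flagged. Fits are
per breed and per direction. Bins with fewer than ``min_bin_count`` members
(or zero variance) are merged with their nearest non-empty neighbour before
fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import DegenerateBinError, DomainError

N_BINS = 20
BIN_WIDTH = 0.05


def bin_assign(frequency: float) -> int:
    """Bin index floor(freq / 0.05); left-closed right-open, freq 1.0 -> bin 19."""
    if not (0.0 < frequency <= 1.0):
        raise DomainError(f"frequency must be in (0, 1], got {frequency}")
    return min(int(frequency / BIN_WIDTH), N_BINS - 1)


@dataclass
class FrequencyBin:
    """A fitted (possibly merged) frequency bin of log-rEHH values."""

    indices: tuple[int, ...]  # original 0-19 bin indices merged into this group
    lo: float
    hi: float
    n: int
    mean: float
    sd: float


def fit_bins(frequencies, rehh_values, min_bin_count: int = 10) -> list[FrequencyBin]:
    """Natural-log-transform rEHH values, group by frequency bin, merge small or
    zero-variance groups with their nearest neighbour, and fit mean/sd."""
    freqs = np.asarray(frequencies, dtype=float)
    vals = np.asarray(rehh_values, dtype=float)
    if freqs.shape != vals.shape:
        raise DomainError("frequencies and rEHH values must align")
    ok = np.isfinite(vals) & (vals > 0)
    freqs, vals = freqs[ok], np.log(vals[ok])
    if len(vals) == 0:
        raise DegenerateBinError("no finite positive rEHH values to fit")
    bins = np.array([bin_assign(f) for f in freqs])

    groups: list[dict] = []
    for b in range(N_BINS):
        members = vals[bins == b]
        if len(members):
            groups.append({"indices": [b], "values": members})

    def needs_merge(g) -> bool:
        return len(g["values"]) < min_bin_count or float(np.std(g["values"])) == 0.0

    while len(groups) > 1 and any(needs_merge(g) for g in groups):
        k = min((i for i, g in enumerate(groups) if needs_merge(g)),
                key=lambda i: (len(groups[i]["values"]), groups[i]["indices"][0]))
        center = np.mean(groups[k]["indices"])
        neighbours = [i for i in (k - 1, k + 1) if 0 <= i < len(groups)]
        j = min(neighbours, key=lambda i: (abs(np.mean(groups[i]["indices"]) - center), i))
        a, b = sorted((k, j))
        merged = {
            "indices": sorted(groups[a]["indices"] + groups[b]["indices"]),
            "values": np.concatenate([groups[a]["values"], groups[b]["values"]]),
        }
        groups[a : b + 1] = [merged]

    out = []
    for g in groups:
        sd = float(np.std(g["values"], ddof=1)) if len(g["values"]) > 1 else 0.0
        if sd == 0.0:
            raise DegenerateBinError("all rEHH values collapse into a zero-variance bin")
        out.append(FrequencyBin(
            indices=tuple(g["indices"]),
            lo=g["indices"][0] * BIN_WIDTH,
            hi=min((g["indices"][-1] + 1) * BIN_WIDTH, 1.0),
            n=len(g["values"]),
            mean=float(np.mean(g["values"])),
            sd=sd,
        ))
    return out


def empirical_p(bin_: FrequencyBin, rehh_value: float, tail: str = "upper") -> tuple[float, float]:
    """One-sided upper-tail p = 1 - Phi((ln rEHH - mean)/sd), with -log10 p."""
    if bin_.sd <= 0:
        raise DegenerateBinError("bin not fitted (sd <= 0)")
    if not (np.isfinite(rehh_value) and rehh_value > 0):
        raise DomainError("rEHH value must be finite and positive")
    z = (math.log(rehh_value) - bin_.mean) / bin_.sd
    if tail == "upper":
        p = float(norm.sf(z))
    elif tail == "two-sided":
        p = float(2 * norm.sf(abs(z)))
    else:
        raise DomainError(f"tail must be 'upper' or 'two-sided', got {tail!r}")
    p = max(p, 1e-300)
    return p, -math.log10(p)


def _bin_lookup(fitted: list[FrequencyBin]) -> dict[int, FrequencyBin]:
    lut = {}
    for fb in fitted:
        for idx in fb.indices:
            lut[idx] = fb
    # map unpopulated bin indices to the nearest fitted group
    for idx in range(N_BINS):
        if idx not in lut:
            lut[idx] = min(fitted, key=lambda fb: min(abs(i - idx) for i in fb.indices))
    return lut


def annotate_significance(df: pd.DataFrame, alpha: float = 0.05, min_bin_count: int = 10,
                          tail: str = "upper", min_freq: float = 0.25) -> pd.DataFrame:
    """Add p-values and significance flags to a per-core-allele scan frame.

    Expects columns ``frequency``, ``rehh_up``, ``rehh_down``. The empirical
    distribution per direction is fitted on every finite positive rEHH value;
    ``retained`` marks frequency > ``min_freq``; an allele is ``significant``
    if retained and p <= alpha in at least one direction.
    """
    if not (0 < alpha < 1):
        raise DomainError(f"alpha must be in (0, 1), got {alpha}")
    out = df.copy()
    for direction in ("up", "down"):
        col = f"rehh_{direction}"
        vals = out[col].to_numpy(dtype=float)
        usable = np.isfinite(vals) & (vals > 0)
        p = np.full(len(out), np.nan)
        nlp = np.full(len(out), np.nan)
        if usable.any():
            fitted = fit_bins(out.loc[usable, "frequency"], vals[usable], min_bin_count)
            lut = _bin_lookup(fitted)
            for i in np.flatnonzero(usable):
                fb = lut[bin_assign(float(out["frequency"].iloc[i]))]
                p[i], nlp[i] = empirical_p(fb, float(vals[i]), tail)
        # infinite/undefined rEHH stay excluded from binning: p remains NaN but
        # the sentinel value itself is carried through in the rehh column
        out[f"p_{direction}"] = p
        out[f"neg_log10_p_{direction}"] = nlp
        out[f"sig_{direction}"] = (p <= alpha) & ~np.isnan(p)
    out["retained"] = out["frequency"] > min_freq
    out["significant"] = out["retained"] & (out["sig_up"] | out["sig_down"])
    return out
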