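"""Depth-only null predictions for POM flux and megafauna biomass.

Flux follows the Martin-curve power law (flux proportional to Z^-0.7, Z in
metres); biomass follows a log-linear depth relation (proportional to
10^(-0.4 Z), Z in kilometres). Enhancement factors are expressed relative
to a reference (plain) depth, so factor(z_ref, z_ref) = 1 and shallower
comparison depths give factors > 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["flux_factor", "biomass_factor", "normalise_to_plain",
           "observed_vs_predicted"]


def _check_depths(z_ref_m: float, z_m) -> None:
    if z_ref_m <= 0 or np.any(np.asarray(z_m) <= 0):
        raise ValueError("depths must be positive")


def flux_factor(z_ref_m: float, z_m, exponent: float = 0.7):
    """Predicted POM flux enhancement (z_ref / z)^exponent."""
    _check_depths(z_ref_m, z_m)
    out = (z_ref_m / np.asarray(z_m, dtype=float)) ** exponent
    return float(out) if np.ndim(z_m) == 0 else out


def biomass_factor(z_ref_m: float, z_m, slope: float = 0.4):
    """Predicted biomass enhancement 10^(slope * (z_ref - z) / 1000)."""
    _check_depths(z_ref_m, z_m)
    out = 10.0 ** (slope * (z_ref_m - np.asarray(z_m, dtype=float)) / 1000.0)
    return float(out) if np.ndim(z_m) == 0 else out


def normalise_to_plain(series: dict, plain_key) -> dict:
    """Divide every value by the plain value (plain maps to exactly 1.0)."""
    if plain_key not in series:
        raise KeyError(f"plain key {plain_key!r} missing from series")
    plain = series[plain_key]
    if not plain > 0:
        raise ValueError("plain value must be positive")
    return {k: v / plain for k, v in series.items()}


def observed_vs_predicted(observed_norm: dict, predictions: dict) -> pd.DataFrame:
    """Observed vs depth-only predicted enhancement factors per key.

    Both inputs are keyed by band/class; ratio = observed / predicted.
    """
    if set(observed_norm) != set(predictions):
        raise KeyError("observed and predicted keys do not match: "
                       f"{sorted(set(observed_norm) ^ set(predictions))}")
    rows = [{"key": k, "observed": observed_norm[k], "predicted": predictions[k],
             "ratio": observed_norm[k] / predictions[k]}
            for k in observed_norm]
    return pd.DataFrame(rows)
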