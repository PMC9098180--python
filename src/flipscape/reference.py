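"""Published kinetic reference data for base flipping in a d(GA)6 duplex.

The packaged table carries, per flipped-out state, the CPDb angle of the
open state, the 300 K free-energy barriers, and the opening/closing rate
constants.  All derived bookkeeping — state lifetimes (reciprocal rates),
equilibrium constants (rate ratios) and order-of-magnitude comparisons —
is recomputed from the rates, never stored.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .kinetics import (equilibrium_constant, lifetimes_from_rates,
                       order_of_magnitude_ratio)

__all__ = ["load_reference_rates", "kinetic_bookkeeping",
           "thymine_decade_ratios"]


def load_reference_rates() -> pd.DataFrame:
    with resources.files("flipscape.data").joinpath(
            "reference_kinetics.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


def kinetic_bookkeeping(rates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Derived kinetics for every flipped-out state in the reference table.

    Adds closed/open state lifetimes and the equilibrium constant for
    opening, all computed from the two rate constants.
    """
    df = (rates if rates is not None else load_reference_rates()).copy()
    lifetimes = [lifetimes_from_rates(ko, kc)
                 for ko, kc in zip(df.k_open_per_s, df.k_close_per_s)]
    df["lifetime_closed_s"] = [lc for lc, _ in lifetimes]
    df["lifetime_open_s"] = [lo for _, lo in lifetimes]
    df["k_eq"] = [equilibrium_constant(ko, kc)
                  for ko, kc in zip(df.k_open_per_s, df.k_close_per_s)]
    return df


def thymine_decade_ratios(rates: pd.DataFrame | None = None) -> dict:
    """Order-of-magnitude separations between thymine opening rates.

    Compares small-angle vs large-angle flipping along the major groove,
    and small-angle minor-groove vs large-angle major-groove flipping
    (the spread that brackets the disagreement between NMR imino-proton
    exchange and fluorescence-correlation experiments).
    """
    df = rates if rates is not None else load_reference_rates()
    t = df[df.base == "T"]
    tmaj = t[t.groove == "major"].sort_values("cpdb_deg", key=abs)
    tmin = t[t.groove == "minor"].sort_values("cpdb_deg", key=abs)
    k_major_small = float(tmaj.iloc[0].k_open_per_s)
    k_major_large = float(tmaj.iloc[-1].k_open_per_s)
    k_minor_small = float(tmin.iloc[0].k_open_per_s)
    return {
        "major_small_vs_major_large": order_of_magnitude_ratio(
            k_major_small, k_major_large),
        "minor_small_vs_major_large": order_of_magnitude_ratio(
            k_minor_small, k_major_large),
    }
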