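"""Packaged activity setups for the phantom measurement campaign.

These are the measured activity concentrations at scan time for the three
phantom fillings (spheres only, 8:1 and 4:1 sphere-to-background contrast) of
each isotope, used throughout the package as realistic operating points.

One of the repeated 8:1 measurements for Tc-99m carries a tabulated ratio
(7.86) that is not reproducible from its own concentration pair
(419.6 / 44.6 = 9.41); it is retained but flagged ``consistent=False`` so
analyses can restrict themselves to self-consistent rows.
"""

from __future__ import annotations

from dataclasses import dataclass

from .phantom import ActivitySetup, realized_ratio

__all__ = ["SetupRecord", "TABLE_SETUPS", "get_setup", "consistent_setups"]


@dataclass(frozen=True)
class SetupRecord:
    """One phantom filling: isotope, setup name, concentrations, tabulated ratio."""

    isotope: str  # 'tc99m' | 'ho166'
    name: str  # 'spheres_only' | '8to1' | '8to1_repeat' | '4to1'
    setup: ActivitySetup
    tabulated_ratio: float | None
    consistent: bool  # tabulated ratio reproducible from the concentrations


def _record(isotope: str, name: str, c_s: float, c_bg: float,
            nominal: float | None, tabulated: float | None) -> SetupRecord:
    setup = ActivitySetup(c_s, c_bg, nominal)
    if tabulated is None or c_bg == 0:
        consistent = True
    else:
        consistent = abs(realized_ratio(setup, ndigits=2) - tabulated) < 0.005
    return SetupRecord(isotope, name, setup, tabulated, consistent)


TABLE_SETUPS: tuple[SetupRecord, ...] = (
    _record("tc99m", "spheres_only", 698.0, 0.0, None, None),
    _record("tc99m", "8to1", 338.8, 39.6, 8.0, 8.56),
    _record("tc99m", "8to1_repeat", 419.6, 44.6, 8.0, 7.86),
    _record("tc99m", "4to1", 213.7, 52.4, 4.0, 4.08),
    _record("ho166", "spheres_only", 1376.0, 0.0, None, None),
    _record("ho166", "8to1", 719.2, 85.7, 8.0, 8.39),
    _record("ho166", "8to1_repeat", 589.5, 74.4, 8.0, 7.92),
    _record("ho166", "4to1", 386.6, 91.5, 4.0, 4.23),
)


def get_setup(isotope: str, name: str) -> SetupRecord:
    for rec in TABLE_SETUPS:
        if rec.isotope == isotope and rec.name == name:
            return rec
    raise KeyError(f"no packaged setup {isotope!r}/{name!r}")


def consistent_setups() -> tuple[SetupRecord, ...]:
    """Setups whose tabulated ratio matches their concentration pair."""
    return tuple(r for r in TABLE_SETUPS if r.consistent)
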