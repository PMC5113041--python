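"""Bundled wild-type validation benchmark.

The package ships three small published benchmark tables comparing a
reference simulation of early C. elegans embryogenesis against wild-type
observational tracking data:

* ``count_benchmark`` — simulated vs observed cell counts sampled every
  five minutes over the first ~160 minutes (30 sampling points; a few
  late, division-dense points pair slightly different simulated and
  observed times, recorded in the ``sim_time``/``obs_time`` columns);
* ``cycle_benchmark`` — born and divided times (seconds) of 12 early
  founder cells, simulated and observed, with the observational born- and
  divided-time SDs;
* ``position_benchmark`` — the 3-D positions of the same 12 founder cells
  at their division time, with the published per-axis deviations.

These tables serve two purposes: frozen expected values for the validation
statistics (count RMSE, cycle RMSE, quadrature cycle SDs, the 60%-of-SD
statistic, per-axis position aggregates), and a worked example of the
report formats.

Note one internal inconsistency of the published position table: the
tabulated x-deviation of cell C (0.0004) does not equal the difference of
its tabulated coordinates (|5.1186 - 5.1119| = 0.0067). The bundled file
keeps the tabulated deviation columns verbatim, and the per-axis
aggregates are computed from those columns; recomputing deviations from
the coordinates changes the x aggregate.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_count_benchmark",
    "load_cycle_benchmark",
    "load_position_benchmark",
]


def _load(name: str, **kwargs) -> pd.DataFrame:
    with resources.files("wormabm.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", **kwargs)


def load_count_benchmark() -> pd.DataFrame:
    """Cell-count benchmark with a ``deviation`` column (|sim - obs|)."""
    df = _load("count_benchmark.tsv")
    df["deviation"] = (df["sim_count"] - df["obs_count"]).abs()
    return df


def load_cycle_benchmark() -> pd.DataFrame:
    """Cycle benchmark indexed by cell name, with derived ``sim_cycle``,
    ``obs_cycle``, quadrature ``obs_cycle_sd`` and ``deviation`` columns."""
    from .validation import cycle_sd

    df = _load("cycle_benchmark.tsv", index_col="name")
    df["sim_cycle"] = df["sim_divided"] - df["sim_born"]
    df["obs_cycle"] = df["obs_divided"] - df["obs_born"]
    df["obs_cycle_sd"] = [
        cycle_sd(row.obs_born_sd, row.obs_divided_sd) for row in df.itertuples()
    ]
    df["deviation"] = (df["sim_cycle"] - df["obs_cycle"]).abs()
    return df


def load_position_benchmark() -> pd.DataFrame:
    """Dividing-position benchmark indexed by cell name. The ``dev_*``
    columns are the published per-axis deviations (kept verbatim; see the
    module docstring for the one row where they differ from the coordinate
    difference)."""
    return _load("position_benchmark.tsv", index_col="name")
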