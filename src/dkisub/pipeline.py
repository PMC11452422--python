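"""Factorial truncation experiment: method × subset × SNR × instance.

For each of ``n_orientations`` random substrate orientations and ``n_noise``
Rician noise draws, the full 100-volume dataset is simulated once; every
subset then extracts its volumes from that same noisy realization — exactly
what happens when a real acquisition is truncated, and what makes
subset-versus-full comparisons paired.  Each extracted dataset is fitted
(positivity-constrained by default), the seven scalar parameters are
derived, and medians/interquartile ranges are aggregated per cell.  The
headline quantity is the relative error of each cell's median against the
fully sampled median at the same SNR:

    rel_error_pct = 100 · |median_subset − median_full| / median_full.

All randomness derives deterministically from ``master_seed`` (sub-streams
keyed by purpose, orientation and noise ids), so reruns are bit-identical
regardless of execution order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import build_design_matrix, fit_batch
from .metrics import PARAMETERS, scalar_metrics_batch
from .scheme import (GradientScheme, SubsetSpec, generate_multishell_scheme,
                     order_incremental_eem, subsample_eem, subsample_random,
                     subsample_sc)
from .substrate import build_default_substrate, simulate_signal

__all__ = [
    "ExperimentConfig",
    "build_reference_scheme",
    "build_subset_indices",
    "run_experiment",
    "relative_error",
    "max_error_summary",
    "export_results",
]

METHODS = ("opt_eem", "opt_sc", "random_trunc")
FRACTIONS = (1.0, 0.95, 0.9, 0.8, 0.7, 0.6, 0.5)
REALISTIC_SNRS = (10, 20, 30, 40, 50)


@dataclass(frozen=True)
class ExperimentConfig:
    """Factorial design of a truncation experiment.

    The full dataset (fraction 1.0) is always carried as the reference even
    when not listed in ``fractions``.
    """

    methods: tuple = METHODS
    fractions: tuple = FRACTIONS
    snr_levels: tuple = (10, 20, 30, 40, 50, 1000)
    n_orientations: int = 100
    n_noise: int = 100
    master_seed: int = 0
    fit_method: str = "constrained"  # "constrained" | "wls"
    signal_model: str = "dki"
    sphere_resolution: int = 10_000
    scheme_restarts: int = 20

    def __post_init__(self):
        fr = tuple(sorted(set(self.fractions) | {1.0}, reverse=True))
        object.__setattr__(self, "fractions", fr)
        if self.fit_method not in ("constrained", "wls"):
            raise ValueError(f"unknown fit_method {self.fit_method!r}")

    @property
    def n_instances(self) -> int:
        return self.n_orientations * self.n_noise

    def to_dict(self) -> dict:
        return {
            "methods": list(self.methods),
            "fractions": list(self.fractions),
            "snr_levels": list(self.snr_levels),
            "n_orientations": self.n_orientations,
            "n_noise": self.n_noise,
            "master_seed": self.master_seed,
            "fit_method": self.fit_method,
            "signal_model": self.signal_model,
            "sphere_resolution": self.sphere_resolution,
            "scheme_restarts": self.scheme_restarts,
        }


def _derived_seed(*keys: int) -> int:
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


def build_reference_scheme(
    master_seed: int = 0, n_restarts: int = 20
) -> GradientScheme:
    """The 100-volume two-shell reference scheme (32 × b1000 + 60 × b2000 +
    8 × b0), EEM-optimized and incrementally ordered."""
    scheme = generate_multishell_scheme(
        n_per_shell={1: 32, 2: 60},
        bvalues={1: 1000.0, 2: 2000.0},
        n_b0=8,
        seed=_derived_seed(master_seed, 1),
        n_restarts=n_restarts,
    )
    return order_incremental_eem(scheme).rebase()


def build_subset_indices(
    scheme: GradientScheme, methods, fractions, master_seed: int = 0
) -> dict:
    """Volume-index arrays (into ``scheme``) for every method × fraction.

    Opt_EEM subsets are prefix truncations; Opt_SC subsets are built
    sequentially (each level from the previous one, hence nested);
    Random_TRUNC uses a single seeded shuffle so its truncation levels are
    nested too.
    """
    out = {}
    descending = sorted({f for f in fractions if f < 1.0}, reverse=True)
    for method in methods:
        previous = None
        random_seed = _derived_seed(master_seed, 7)
        for fraction in descending:
            spec = SubsetSpec.from_scheme(scheme, fraction)
            if method == "opt_eem":
                sub = subsample_eem(scheme, spec)
            elif method == "opt_sc":
                sub = subsample_sc(scheme, spec, previous=previous)
                previous = sub
            elif method == "random_trunc":
                sub = subsample_random(scheme, spec, seed=random_seed)
            else:
                raise ValueError(f"unknown method {method!r}")
            out[(method, fraction)] = sub.source_index.copy()
    return out


def run_experiment(
    config: ExperimentConfig,
    scheme: GradientScheme | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run the factorial experiment and return the tidy metric table.

    Columns: method, fraction, snr, parameter, statistic ∈ {median, iqr},
    value, flagged (True when > 1% of the cell's fits failed).  Reference
    rows carry method ``"full"`` and fraction 1.0.  Relative errors are
    added by :func:`relative_error`.
    """
    if scheme is None:
        scheme = build_reference_scheme(config.master_seed, config.scheme_restarts)
    n_vols = scheme.n_volumes
    subsets = build_subset_indices(
        scheme, config.methods, config.fractions, config.master_seed
    )
    cells = [("full", 1.0, np.arange(n_vols))] + [
        (m, f, idx) for (m, f), idx in sorted(subsets.items())
    ]
    designs = {}
    sub_schemes = {}
    for method, fraction, idx in cells:
        key = tuple(idx.tolist())
        if key not in designs:
            sub = scheme.take(idx)
            sub_schemes[key] = sub
            designs[key] = build_design_matrix(sub)

    # noiseless full-scheme signals per orientation
    rng_orient = np.random.default_rng([config.master_seed, 2])
    noiseless = np.empty((config.n_orientations, n_vols))
    from .sphere import random_rotation

    for o in range(config.n_orientations):
        sub = build_default_substrate(rotation=random_rotation(rng_orient))
        noiseless[o] = simulate_signal(
            sub, scheme, s0=1.0, model=config.signal_model
        ).signals

    # shared noise quadratures: each instance's realization is drawn once and
    # scaled per SNR, so subsets and SNR levels see the same underlying noise
    eps = np.empty((config.n_orientations, config.n_noise, 2, n_vols))
    for o in range(config.n_orientations):
        for j in range(config.n_noise):
            eps[o, j] = np.random.default_rng(
                [config.master_seed, 3, o, j]
            ).standard_normal((2, n_vols))

    records = []
    constrained = config.fit_method == "constrained"
    for snr in config.snr_levels:
        sigma = 1.0 / float(snr)
        noisy = np.hypot(
            noiseless[:, None, :] + sigma * eps[:, :, 0, :],
            sigma * eps[:, :, 1, :],
        ).reshape(config.n_instances, n_vols)
        for method, fraction, idx in cells:
            key = tuple(idx.tolist())
            coeffs, flags = fit_batch(
                noisy[:, idx], sub_schemes[key],
                constrained=constrained, design=designs[key],
            )
            failed = float(np.mean(flags == "failed"))
            flagged = failed > 0.01
            vals = scalar_metrics_batch(coeffs, config.sphere_resolution)
            med = np.nanmedian(vals, axis=0)
            q75, q25 = np.nanpercentile(vals, [75, 25], axis=0)
            for p, parameter in enumerate(PARAMETERS):
                records.append((method, fraction, snr, parameter, "median",
                                med[p], flagged))
                records.append((method, fraction, snr, parameter, "iqr",
                                q75[p] - q25[p], flagged))
            if progress:
                print(f"snr={snr} {method} fraction={fraction} "
                      f"failed={failed:.3%}", flush=True)
    table = pd.DataFrame(
        records,
        columns=["method", "fraction", "snr", "parameter", "statistic",
                 "value", "flagged"],
    )
    return relative_error(table)


def relative_error(table: pd.DataFrame) -> pd.DataFrame:
    """Append paired relative-error statistics against the full dataset.

    For every (method, fraction, snr, parameter) median, adds
    ``rel_error_signed_pct`` = 100·(median − median_full)/median_full and its
    absolute value ``rel_error_pct``; the fraction-1.0 reference rows get
    exactly 0.  Cells whose full-data median is zero are flagged and carry
    NaN errors.
    """
    med = table[table.statistic == "median"]
    ref = med[(med.method == "full")].set_index(["snr", "parameter"]).value
    if ref.empty:
        raise ValueError("table lacks the fraction-1.0 reference rows")
    new_rows = []
    for row in med.itertuples(index=False):
        full_val = ref.get((row.snr, row.parameter), np.nan)
        if full_val == 0 or not np.isfinite(full_val):
            signed = np.nan
            flagged = True
        else:
            signed = 100.0 * (row.value - full_val) / full_val
            flagged = row.flagged
        if row.method == "full":
            signed = 0.0
        for stat, value in [("rel_error_signed_pct", signed),
                            ("rel_error_pct", abs(signed))]:
            new_rows.append((row.method, row.fraction, row.snr, row.parameter,
                             stat, value, flagged))
    extra = pd.DataFrame(new_rows, columns=table.columns)
    base = table[~table.statistic.isin(["rel_error_pct", "rel_error_signed_pct"])]
    return pd.concat([base, extra], ignore_index=True)


def max_error_summary(
    table: pd.DataFrame,
    parameter: str,
    methods=None,
    fractions=None,
    snr_levels=None,
) -> float:
    """Maximum relative error (%) of one parameter over a scope of cells."""
    sel = table[(table.statistic == "rel_error_pct")
                & (table.parameter == parameter)]
    if methods is not None:
        sel = sel[sel.method.isin(methods)]
    if fractions is not None:
        sel = sel[sel.fraction.isin(fractions)]
    if snr_levels is not None:
        sel = sel[sel.snr.isin(snr_levels)]
    if sel.empty:
        raise ValueError("empty scope for max_error_summary")
    return float(sel.value.max())


def export_results(table: pd.DataFrame, path, config: ExperimentConfig | None = None):
    """Write medians.csv, iqr.csv, rel_error.csv (+ run manifest) to ``path``.

    Floats are written with 6 significant digits so exports diff cleanly;
    re-reading and re-writing an export is byte-identical.
    """
    import pathlib

    if table.empty:
        raise ValueError("refusing to export an empty table")
    out = pathlib.Path(path)
    out.mkdir(parents=True, exist_ok=True)
    groups = {
        "medians.csv": table[table.statistic == "median"],
        "iqr.csv": table[table.statistic == "iqr"],
        "rel_error.csv": table[table.statistic.isin(
            ["rel_error_pct", "rel_error_signed_pct"])],
    }
    for name, frame in groups.items():
        frame.to_csv(out / name, index=False, float_format="%.6g")
    manifest = {"version": _package_version()}
    if config is not None:
        manifest["config"] = config.to_dict()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("dkisub")
    except PackageNotFoundError:
        return "unknown"
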