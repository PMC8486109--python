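"""CSV input/output, run configuration, and the end-to-end pipeline.

Input layout (comma-separated, UTF-8, header row, ``.`` decimal separator),
following the data-exchange conventions of the SIMM ecosystem:

* sources file — one row per source:
  ``source, mean_<iso>, sd_<iso>`` repeated per isotope;
* TEFs file — same layout, one row per source (optional; zero TEFs assumed
  when absent);
* mixtures file — one row per consumer, one column per isotope, plus an
  optional leading ``id`` column.

Isotope names are matched case-insensitively after stripping a cosmetic
delta prefix (``d13C``, ``D13C`` and ``13C`` all refer to the same column).
Malformed numerics are rejected with an error naming file, row and column —
never silently coerced.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .diagnostics import DiagnosticsReport, full_report
from .model import MixingSpace, MixtureData, ModelSpec
from .samplers import PosteriorDraws, default_ladder, sample_beta, sample_ordinary

__all__ = [
    "SchemaError", "IsoTable", "RunConfig",
    "read_sources", "read_tefs", "read_mixtures", "load_inputs",
    "write_fixture_csvs", "write_draws_csv", "read_draws_csv",
    "run_pipeline",
]

logger = logging.getLogger("betasimm")


class SchemaError(ValueError):
    """Malformed or inconsistent input file."""


def normalize_isotope(name: str) -> str:
    """Canonical isotope key: case-folded, delta prefix stripped."""
    s = str(name).strip().lstrip("δΔ")  # delta / Delta
    low = s.lower()
    if low.startswith("d") and len(low) > 1 and low[1].isdigit():
        low = low[1:]
    return low


def _parse_cell(raw, path, row, col) -> float:
    try:
        val = float(raw)
    except (TypeError, ValueError):
        raise SchemaError(
            f"{path}: row {row}, column {col!r}: non-numeric value {raw!r}")
    if not np.isfinite(val):
        raise SchemaError(
            f"{path}: row {row}, column {col!r}: non-finite value {raw!r}")
    return val


@dataclass(frozen=True)
class IsoTable:
    """Per-source means and SDs for a set of isotopes (sources or TEFs)."""

    source_names: tuple[str, ...]
    isotope_names: tuple[str, ...]   # as written in the file
    mean: np.ndarray                 # (K, J)
    sd: np.ndarray                   # (K, J)

    @property
    def isotope_keys(self) -> tuple[str, ...]:
        return tuple(normalize_isotope(n) for n in self.isotope_names)


def _read_iso_table(path) -> IsoTable:
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    cols = [c.strip() for c in df.columns]
    if not cols or cols[0].lower() != "source":
        raise SchemaError(f"{path}: first column must be 'source'")
    mean_cols = [c for c in cols[1:] if c.lower().startswith("mean_")]
    sd_cols = [c for c in cols[1:] if c.lower().startswith("sd_")]
    extra = [c for c in cols[1:] if c not in mean_cols and c not in sd_cols]
    if extra:
        raise SchemaError(
            f"{path}: unexpected columns {extra}; expected mean_<iso>/sd_<iso>")
    isos = [c.split("_", 1)[1] for c in mean_cols]
    sd_keys = {normalize_isotope(c.split('_', 1)[1]): c for c in sd_cols}
    if set(sd_keys) != {normalize_isotope(i) for i in isos} or \
            len(sd_cols) != len(mean_cols):
        raise SchemaError(
            f"{path}: mean_/sd_ columns do not describe the same isotopes")
    names = [str(s).strip() for s in df.iloc[:, 0]]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise SchemaError(f"{path}: duplicate source name(s) {dup}")
    K, J = len(names), len(isos)
    mean = np.empty((K, J))
    sd = np.empty((K, J))
    df.columns = cols
    for j, iso in enumerate(isos):
        mcol = mean_cols[j]
        scol = sd_keys[normalize_isotope(iso)]
        for i in range(K):
            mean[i, j] = _parse_cell(df[mcol].iloc[i], path, i + 2, mcol)
            sd[i, j] = _parse_cell(df[scol].iloc[i], path, i + 2, scol)
    if np.any(sd < 0):
        raise SchemaError(f"{path}: negative SD entries")
    return IsoTable(tuple(names), tuple(isos), mean, sd)


def read_sources(path) -> IsoTable:
    """Read per-source isotope means/SDs (``source, mean_<iso>, sd_<iso>``)."""
    return _read_iso_table(path)


def read_tefs(path) -> IsoTable:
    """Read per-source TEF means/SDs; same layout as the sources file."""
    return _read_iso_table(path)


def read_mixtures(path) -> tuple[tuple[str, ...], tuple[str, ...], np.ndarray]:
    """Read consumer measurements.

    Returns (consumer_ids, isotope_names_as_written, values).  Columns are
    one isotope each; a leading ``id`` column is honoured when present.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    cols = [c.strip() for c in df.columns]
    df.columns = cols
    if not cols:
        raise SchemaError(f"{path}: empty mixtures file")
    if cols[0].lower() in ("id", "consumer", "consumer_id"):
        ids = tuple(str(s).strip() for s in df.iloc[:, 0])
        iso_cols = cols[1:]
    else:
        ids = tuple(f"consumer_{i + 1}" for i in range(len(df)))
        iso_cols = cols
    if not iso_cols:
        raise SchemaError(f"{path}: no isotope columns")
    if len(df) < 1:
        raise SchemaError(f"{path}: no consumer rows")
    values = np.empty((len(df), len(iso_cols)))
    for j, col in enumerate(iso_cols):
        for i in range(len(df)):
            values[i, j] = _parse_cell(df[col].iloc[i], path, i + 2, col)
    return ids, tuple(iso_cols), values


def load_inputs(mixtures_path, sources_path,
                tefs_path=None) -> tuple[MixingSpace, MixtureData]:
    """Assemble validated model inputs from the three CSV files.

    Isotope sets must agree across files (after normalization); the isotope
    order of the sources file is canonical.  A missing TEF file defaults to
    zero TEFs with a logged warning.
    """
    src = read_sources(sources_path)
    ids, mix_isos, values = read_mixtures(mixtures_path)
    src_keys = src.isotope_keys
    if len(set(src_keys)) != len(src_keys):
        raise SchemaError(f"{sources_path}: duplicate isotope columns")
    mix_keys = tuple(normalize_isotope(n) for n in mix_isos)
    if set(mix_keys) != set(src_keys):
        raise SchemaError(
            f"isotopes in {mixtures_path} ({sorted(mix_keys)}) do not match "
            f"those in {sources_path} ({sorted(src_keys)})")
    order = [mix_keys.index(k) for k in src_keys]
    values = values[:, order]
    if tefs_path is not None:
        tef = read_tefs(tefs_path)
        if tef.source_names != src.source_names:
            raise SchemaError(
                f"{tefs_path}: source names/order do not match {sources_path}")
        if set(tef.isotope_keys) != set(src_keys):
            raise SchemaError(
                f"{tefs_path}: isotopes do not match {sources_path}")
        torder = [tef.isotope_keys.index(k) for k in src_keys]
        tef_mean = tef.mean[:, torder]
        tef_sd = tef.sd[:, torder]
    else:
        logger.warning("no TEF file given; assuming zero trophic enrichment")
        tef_mean = np.zeros_like(src.mean)
        tef_sd = np.zeros_like(src.sd)
    space = MixingSpace(src.source_names, src.isotope_names,
                        src.mean, src.sd, tef_mean, tef_sd)
    return space, MixtureData(values, ids)


def write_fixture_csvs(directory, space: MixingSpace, data: MixtureData):
    """Write (mixtures, sources, tefs) CSVs in the reader's dialect."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    src_cols: dict = {"source": list(space.source_names)}
    tef_cols: dict = {"source": list(space.source_names)}
    for j, iso in enumerate(space.isotope_names):
        src_cols[f"mean_{iso}"] = space.source_mean[:, j]
        src_cols[f"sd_{iso}"] = space.source_sd[:, j]
        tef_cols[f"mean_{iso}"] = space.tef_mean[:, j]
        tef_cols[f"sd_{iso}"] = space.tef_sd[:, j]
    sources_path = directory / "sources.csv"
    tefs_path = directory / "tefs.csv"
    mixtures_path = directory / "mixtures.csv"
    pd.DataFrame(src_cols).to_csv(sources_path, index=False)
    pd.DataFrame(tef_cols).to_csv(tefs_path, index=False)
    mix = pd.DataFrame(data.values, columns=list(space.isotope_names))
    mix.insert(0, "id", list(data.consumer_ids))
    mix.to_csv(mixtures_path, index=False)
    return mixtures_path, sources_path, tefs_path


def write_draws_csv(path, draws: PosteriorDraws) -> None:
    """Flat draw table: source columns, scale columns, chain, beta."""
    df = draws.to_frame()
    df["beta"] = draws.beta
    df.to_csv(path, index=False)


def read_draws_csv(path) -> PosteriorDraws:
    df = pd.read_csv(path)
    if "beta" not in df.columns or "chain" not in df.columns:
        raise SchemaError(f"{path}: draw files need 'beta' and 'chain' columns")
    beta = float(df["beta"].iloc[0])
    chain = df["chain"].to_numpy()
    body = df.drop(columns=["beta", "chain"])
    # scales are the trailing eps_*/xi_* columns; everything before is a source
    scale_cols = [c for c in body.columns
                  if c.startswith("eps_") or c.startswith("xi_")]
    source_cols = [c for c in body.columns if c not in scale_cols]
    return PosteriorDraws(
        p_draws=body[source_cols].to_numpy(),
        scale_draws=body[scale_cols].to_numpy() if scale_cols
        else np.ones((len(body), 1)),
        beta=beta, n_chains=int(chain.max()) + 1, seed=-1,
        source_names=tuple(source_cols), scale_names=tuple(scale_cols),
        chain_index=chain)


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    mixtures_path: str
    sources_path: str
    seed: int
    tefs_path: str | None = None
    error_model: str = "siar_residual"
    beta: float = 1000.0
    n_iter: int = 100_000
    n_chains: int = 4
    n_keep: int = 10_000
    hdi_mass: float = 0.95
    out_dir: str = "."
    write_draws: bool = False
    make_plot: bool = False

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is required (no silent nondeterminism)")
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not 0 < self.hdi_mass < 1:
            raise ValueError("hdi_mass must lie in (0, 1)")


def run_pipeline(config: RunConfig) -> DiagnosticsReport:
    """Full workflow: read inputs, sample both posteriors, write the report.

    Writes ``report.json`` (deterministic for a fixed config and seed),
    ``run_log.json`` (config, resolved ladder, acceptance rates, convergence
    statistics), optional draw CSVs, and an optional overlay plot.
    """
    space, data = load_inputs(config.mixtures_path, config.sources_path,
                              config.tefs_path)
    spec = ModelSpec(error_model=config.error_model, beta=config.beta)
    ordinary = sample_ordinary(data, space, spec, n_iter=config.n_iter,
                               n_chains=config.n_chains, seed=config.seed,
                               n_keep=config.n_keep)
    tempered = sample_beta(data, space, spec, n_iter=config.n_iter,
                           n_chains=config.n_chains, seed=config.seed + 1,
                           n_keep=config.n_keep)
    report = full_report(ordinary, tempered, mass=config.hdi_mass)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json() + "\n")
    run_log = {
        "config": dataclasses.asdict(config),
        "resolved_ladder": tempered.diagnostics.get("ladder")
        or default_ladder(config.beta),
        "ordinary_diagnostics": _jsonable(ordinary.diagnostics),
        "tempered_diagnostics": _jsonable(tempered.diagnostics),
    }
    (out / "run_log.json").write_text(
        json.dumps(run_log, indent=2, sort_keys=True) + "\n")
    if config.write_draws:
        write_draws_csv(out / "draws_ordinary.csv", ordinary)
        write_draws_csv(out / "draws_beta.csv", tempered)
    if config.make_plot:
        from .plotting import overlay_plot

        overlay_plot(ordinary, tempered, out / "overlay.png",
                     mass=config.hdi_mass)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj
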