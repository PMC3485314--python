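"""Output writers: per-draw CSV, summary tables (JSON + aligned text), manifest."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from . import __version__
from .config import LifeHistoryConfig, serialize_config
from .montecarlo import EnsembleResult, SUMMARY_ROWS, summarize

__all__ = ["write_summary", "write_draws", "write_manifest", "write_run"]


def write_summary(ens: EnsembleResult, path) -> dict:
    """Write the ensemble summary as JSON (and a readable .txt twin).

    One row per quantity (M0, W_bpr, alpha, r, h); columns: 5/25/50/75/95%
    quantiles (linear interpolation), mean, sd.
    """
    if any(len(getattr(ens, a)) == 0 for a in ("M0", "r", "alpha", "W_bpr", "h")):
        raise ValueError("cannot summarize an empty ensemble")
    table = summarize(ens)
    payload = {
        "scenario": ens.scenario,
        "seed": ens.seed,
        "quantile_method": "linear",
        "rows": SUMMARY_ROWS,
        "summary": {name: {c: float(table.loc[name, c]) for c in table.columns}
                    for name in table.index},
        "spearman": {k: float(v) for k, v in ens.spearman()["spearman"].items()},
        "rejection": ens.rejection,
        "meta": ens.meta,
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2))
    path.with_suffix(".txt").write_text(table.to_string(float_format=lambda v: f"{v:.4g}") + "\n")
    return payload


def write_draws(ens: EnsembleResult, path) -> None:
    ens.draws_frame().to_csv(path, index=False)


def _config_hash(cfg: LifeHistoryConfig) -> str:
    return hashlib.sha256(serialize_config(cfg).encode()).hexdigest()[:16]


def write_manifest(cfg: LifeHistoryConfig, ens: EnsembleResult, outdir,
                   files: list[str]) -> None:
    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(cfg),
        "seed": ens.seed,
        "scenario": ens.scenario,
        "draw_counts": ens.meta,
        "outputs": files,
    }
    (Path(outdir) / "manifest.json").write_text(json.dumps(manifest, indent=2))


def write_run(cfg: LifeHistoryConfig, ens: EnsembleResult, outdir) -> list[str]:
    """Write draws.csv, summary.json/.txt and manifest.json under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_draws(ens, outdir / "draws.csv")
    write_summary(ens, outdir / "summary.json")
    files = ["draws.csv", "summary.json", "summary.txt", "manifest.json"]
    write_manifest(cfg, ens, outdir, files)
    return files
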