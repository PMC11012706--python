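"""Report writing and run-comparison utilities.

A run directory contains everything needed to re-derive any table cell:
the sweep grid per weight assignment (TSV, one row per threshold k), the
weight tables (TSV), the winner summary (JSON), the full audit report
(JSON: fold assignments and per-fold selector outputs), an optional
alteration-analysis TSV, and a manifest recording the configuration and
library versions. Stage timings go to the logger, not into the run
directory, so reruns with the same seed produce byte-identical trees.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ProfwiseReport

SWEEP_FLOAT_FMT = "%.6f"


def _versions() -> dict[str, str]:
    import sklearn

    return {
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
    }


def write_report(
    report: ProfwiseReport,
    outdir: str | Path,
    alteration: pd.DataFrame | None = None,
    config_echo: dict | None = None,
) -> list[Path]:
    """Write all run artifacts into ``outdir``; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for label, sr in report.sweeps.items():
        path = outdir / f"sweep_{label}.tsv"
        sr.to_frame().to_csv(path, sep="\t", index=False, float_format=SWEEP_FLOAT_FMT)
        written.append(path)

    for label, wt in report.weight_tables.items():
        path = outdir / f"weights_{label}.tsv"
        rows = sorted(wt.weights.items(), key=lambda kv: (-kv[1], kv[0]))
        pd.DataFrame(rows, columns=["feature_id", "weight"]).to_csv(
            path, sep="\t", index=False
        )
        written.append(path)

    path = outdir / "winner.json"
    path.write_text(json.dumps(report.winner_summary(), indent=2, sort_keys=True))
    written.append(path)

    path = outdir / "run_report.json"
    path.write_text(report.to_json())
    written.append(path)

    if alteration is not None:
        path = outdir / "alteration.tsv"
        alteration.to_csv(path, sep="\t", index=False, float_format="%.6f")
        written.append(path)

    manifest = {
        "versions": _versions(),
        "task": report.task,
        "n_folds": report.config.n_folds,
        "seed": report.config.seed,
        "mrmr": asdict(report.config.mrmr),
        "lasso": asdict(report.config.lasso),
        "nested_evaluation": report.config.nested_evaluation,
    }
    if config_echo:
        manifest["run_config"] = config_echo
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    written.append(path)
    return written


# ---------------------------------------------------------------------------
# Run comparison (shared-feature intersections)
# ---------------------------------------------------------------------------


def _load_winner(path: str | Path) -> dict:
    path = Path(path)
    if path.is_dir():
        path = path / "winner.json"
    try:
        data = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ValueError(f"cannot read winner report at {path}: {exc}") from exc
    if "features" not in data:
        raise ValueError(f"{path} does not contain a winner feature list")
    return data


def compare_runs(paths) -> pd.DataFrame:
    """Pairwise and overall intersections of winner feature lists.

    Accepts 2-4 run directories (or winner.json paths). Intersections are
    computed both by feature ID and by gene symbol; with many-to-one
    ID -> symbol maps the symbol-level overlap can only be larger or equal.
    """
    paths = list(paths)
    if not 2 <= len(paths) <= 4:
        raise ValueError("compare_runs takes between 2 and 4 reports")
    winners = [_load_winner(p) for p in paths]
    names = [Path(p).stem if Path(p).suffix else Path(p).name for p in paths]
    id_sets = [set(w["features"]) for w in winners]
    sym_sets = [
        {w.get("gene_symbols", {}).get(f, f) for f in w["features"]} for w in winners
    ]

    rows = []

    def add(label, sets_a, sets_b=None):
        inter_ids = set.intersection(*sets_a)
        inter_syms = set.intersection(*sets_b) if sets_b else None
        rows.append(
            {
                "comparison": label,
                "n_shared_ids": len(inter_ids),
                "shared_ids": ";".join(sorted(inter_ids)),
                "n_shared_symbols": len(inter_syms) if inter_syms is not None else None,
                "shared_symbols": ";".join(sorted(inter_syms)) if inter_syms else "",
            }
        )

    for i in range(len(paths)):
        for j in range(i + 1, len(paths)):
            add(
                f"{names[i]} & {names[j]}",
                [id_sets[i], id_sets[j]],
                [sym_sets[i], sym_sets[j]],
            )
    if len(paths) > 2:
        add("all", id_sets, sym_sets)
    return pd.DataFrame(rows)
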