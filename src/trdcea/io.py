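"""Result writers and run manifests.

Every pipeline command writes its tabular outputs as plain CSV (UTF-8,
comma-separated, ``.`` decimal, header row, no thousands separators) plus
a JSON run manifest recording the package version, input-file digests,
settings snapshot, seeds and the list of files written, so any
deterministic output can be reproduced from its manifest.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from .engine import CohortTrace, StrategyOutcome
from .frontier import FrontierResult, icer
from .parameters import EconomicSettings

__all__ = [
    "file_digest",
    "write_manifest",
    "outcomes_frame",
    "write_outcomes",
    "write_comparisons",
    "write_frontier",
    "write_trace",
]


def file_digest(path: str | Path) -> str:
    """SHA-256 hex digest of a file's bytes."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    out_dir: str | Path,
    inputs: dict[str, str | Path],
    settings: EconomicSettings,
    outputs: list[str | Path],
    seeds: dict[str, int] | None = None,
    extra: dict | None = None,
) -> Path:
    """Write ``manifest.json`` into ``out_dir`` and return its path."""
    from . import __version__

    out_dir = Path(out_dir)
    doc = {
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "package_version": __version__,
        "inputs": {
            name: {"path": str(p), "sha256": file_digest(p)}
            for name, p in inputs.items()
        },
        "settings": asdict(settings),
        "seeds": seeds or {},
        "outputs": [str(Path(p).name) for p in outputs],
    }
    if extra:
        doc.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(doc, indent=1))
    return path


def outcomes_frame(outcomes: dict[str, StrategyOutcome]) -> pd.DataFrame:
    rows = []
    for name, o in outcomes.items():
        row = {
            "strategy": name,
            "cost": o.cost,
            "qaly": o.qaly,
            "cost_undiscounted": o.cost_undiscounted,
            "qaly_undiscounted": o.qaly_undiscounted,
        }
        row.update({f"cost_{k}": v for k, v in o.cost_components.items()})
        row.update({f"years_{k}": v for k, v in o.time_in_state_years.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def write_outcomes(outcomes: dict[str, StrategyOutcome], path: str | Path) -> Path:
    path = Path(path)
    outcomes_frame(outcomes).to_csv(path, index=False)
    return path


def write_comparisons(
    outcomes: dict[str, StrategyOutcome], reference: str, path: str | Path
) -> Path:
    """All pairwise comparisons against the reference strategy."""
    rows = []
    ref = outcomes[reference]
    for name, o in outcomes.items():
        if name == reference:
            continue
        c = icer(o, ref)
        rows.append(
            {
                "target": c.target,
                "reference": c.reference,
                "delta_cost": c.delta_cost,
                "delta_qaly": c.delta_qaly,
                "icer": "" if c.icer is None else c.icer,
                "label": c.label,
            }
        )
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_frontier(result: FrontierResult, path: str | Path) -> Path:
    rows = []
    for name in result.order:
        o = result.outcomes[name]
        rows.append(
            {
                "strategy": name,
                "cost": o.cost,
                "qaly": o.qaly,
                "label": result.labels[name],
                "icer_vs_previous": result.sequential_icers.get(name, ""),
            }
        )
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_trace(trace: CohortTrace, path: str | Path) -> Path:
    """One row per cycle, one column per named state."""
    df = pd.DataFrame(trace.occupancy, columns=trace.space.labels)
    df.insert(0, "cycle", range(trace.occupancy.shape[0]))
    path = Path(path)
    df.to_csv(path, index=False)
    return path
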