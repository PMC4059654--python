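"""End-to-end analysis runs: fit several variants, compare, report.

Every run writes its configuration, seeds and package version into a
manifest alongside the outputs, so a run can be re-executed bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .dataset import KineticDataset, read_dataset
from .fitting import FitResult, fit_model
from .parameters import save_parameters
from .protocols import AssayProtocol, default_protocols
from .selection import ComparisonTable, ProfileCI, comparison_table, profile_ci
from .topology import MODEL_IDS, topology


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    dataset_path: str
    model_ids: tuple[str, ...] = ("1", "2s")
    seed: int = 0
    n_starts: int = 20
    output_dir: str = "cardiokin_run"
    profile_cis: bool = False
    alpha: float = 0.05
    basal_rate: float = 0.0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not self.model_ids:
            raise ValueError("no models requested")
        unknown = set(self.model_ids) - set(MODEL_IDS)
        if unknown:
            raise ValueError(f"unknown model ids: {sorted(unknown)}")
        if not Path(self.dataset_path).exists():
            raise FileNotFoundError(self.dataset_path)


@dataclass
class PipelineOutput:
    fits: dict[str, FitResult]
    comparison: ComparisonTable
    profile_cis: dict[str, dict[str, ProfileCI]] = field(default_factory=dict)


def run_full_pipeline(config: RunConfig) -> PipelineOutput:
    """Fit every requested variant to the dataset and compare them."""
    config.validate()
    dataset = read_dataset(config.dataset_path)
    protocols = default_protocols(basal_rate=config.basal_rate)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    fits: dict[str, FitResult] = {}
    for mid in config.model_ids:
        fits[mid] = fit_model(mid, dataset, protocols, seed=config.seed,
                              n_starts=config.n_starts)
        with open(out_dir / f"fit_{mid}.json", "w") as fh:
            json.dump(fits[mid].to_dict(), fh, indent=1)
        save_parameters(out_dir / f"params_{mid}.json", fits[mid].params,
                        topology(mid))

    table = comparison_table(fits)
    table.to_csv(out_dir / "comparison.csv")
    table.f_tests.to_csv(out_dir / "f_tests.csv", index=False)
    (out_dir / "comparison.txt").write_text(table.to_text() + "\n")

    cis: dict[str, dict[str, ProfileCI]] = {}
    if config.profile_cis:
        for mid, fit in fits.items():
            cis[mid] = {name: profile_ci(fit, name, dataset, protocols,
                                         alpha=config.alpha)
                        for name in topology(mid).free_parameters}
        with open(out_dir / "profile_cis.json", "w") as fh:
            json.dump({m: {p: dataclasses.asdict(ci) for p, ci in d.items()}
                       for m, d in cis.items()}, fh, indent=1)

    manifest = {
        "config": dataclasses.asdict(config),
        "cardiokin_version": __version__,
        "python": platform.python_version(),
        "dataset_rows": dataset.n,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return PipelineOutput(fits=fits, comparison=table, profile_cis=cis)
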