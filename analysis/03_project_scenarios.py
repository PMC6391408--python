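#!/usr/bin/env python
"""Project end-of-century TN loading for all six SSP-RCP scenarios.

Runs the full pipeline — land-management-only and combined (with
paired-RCP precipitation) projections relative to the 1976-2005 historical
baseline — and reports percent changes with ensemble spread and robustness
for CONUS, the MARB-like basin, and the Northeast-like region. Results
land under results/projections/.
"""

from pathlib import Path

from tnflux.io import RunConfig, run_pipeline, setup_logging
from tnflux.scenarios import SCENARIOS

OUT = Path(__file__).resolve().parent.parent / "results" / "projections"
SEED = 0


def main() -> None:
    setup_logging("WARNING")
    config = RunConfig(outdir=str(OUT), seed=SEED, scenarios=tuple(SCENARIOS))
    result = run_pipeline(config)
    changes = result["changes"]

    conus = changes[changes.region == "CONUS"].pivot(
        index="scenario", columns="run", values="percent_change"
    )
    print("end-of-century CONUS percent change vs 1976-2005:")
    print(conus.round(1).to_string())
    lo = changes[(changes.region == "CONUS") & (changes.run == "land_only")]
    print(
        f"land-management-only range: {lo.percent_change.min():+.0f}% to "
        f"{lo.percent_change.max():+.0f}% across {len(lo)} scenarios"
    )
    co = changes[(changes.region == "CONUS") & (changes.run == "combined")]
    print(f"with precipitation change: {co.percent_change.min():+.0f}% to {co.percent_change.max():+.0f}%")
    print(f"tables written to {OUT}")


if __name__ == "__main__":
    main()
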