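#!/usr/bin/env python
"""Clean the raw localizations: speed filter, sd filter, median smoother.

Reads results/analysis/data/localizations.csv, writes the cleaned tracks and
a per-tag stage report.  With the generator's modest localization error the
filters should remove little; the counts verify that the cleaning is not
destroying real movement.
"""

import json
from pathlib import Path

from knotflight import io as kio
from knotflight.config import PipelineConfig
from knotflight.tracks import StageReport, preprocess

DATA = Path("results/analysis/data")
OUT = Path("results/analysis")


def main() -> None:
    cfg = PipelineConfig.from_yaml(DATA / "config.yaml")
    tracks = kio.read_localizations(DATA / "localizations.csv")
    cleaned, reports = [], []
    for tr in tracks:
        rep = StageReport(tr.tag_id)
        cleaned.append(preprocess(tr, cfg.speed_threshold, cfg.sd_threshold,
                                  cfg.smooth_window, report=rep))
        reports.append(rep.as_dict())
    kio.write_localizations(cleaned, OUT / "localizations_clean.csv")
    with open(OUT / "preprocess_report.json", "w") as fh:
        json.dump(reports, fh, indent=1)

    n_in = sum(r["n_input"] for r in reports)
    n_speed = sum(r["n_speed_removed"] for r in reports)
    n_sd = sum(r["n_sd_removed"] for r in reports)
    n_out = sum(r["n_output"] for r in reports)
    print(f"{len(tracks)} tracks: {n_in} fixes in, {n_speed} removed by the "
          f"100 m/s rule, {n_sd} by the 150 m sd rule, {n_out} out")
    assert n_in == n_out + n_speed + n_sd


if __name__ == "__main__":
    main()
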