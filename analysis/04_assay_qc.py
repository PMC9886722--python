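#!/usr/bin/env python
"""Assay-quality assessment of the simulated screen.

Per-plate QC verdicts (control separation, replicate CVs, clamped and
below-floor well counts) plus the Z-factor of each intervention arm
against the untreated arm at every post-anchor age day, on the raw PI
fluorescence channel.  Writes qc_report.json and zfactors.csv.
"""
import dataclasses
import json
from pathlib import Path

import click
import pandas as pd

from picls.errors import PiclsError
from picls.plate_io import Role, read_long_table
from picls.qc import plate_qc, z_factor

OUT = Path(__file__).resolve().parent.parent / "results"


@click.command()
def main():
    records = read_long_table(OUT / "plates.csv")
    reports = plate_qc(records)
    verdicts = {r.verdict for r in reports}
    click.echo(f"{len(reports)} plate/day QC reports; verdicts: {sorted(verdicts)}")
    (OUT / "qc_report.json").write_text(json.dumps(
        [dataclasses.asdict(r) for r in reports], indent=2, default=str) + "\n")

    samples = [r for r in records if r.role is Role.sample]
    days = sorted({r.age_day for r in samples if r.age_day > 1})
    arms = sorted({r.condition for r in samples if r.compound is not None},
                  key=str)
    rows = []
    for day in days:
        ctrl = [r.fluorescence for r in samples
                if r.age_day == day and r.compound is None]
        for cond in arms:
            treat = [r.fluorescence for r in samples
                     if r.age_day == day and r.condition == cond]
            try:
                res = z_factor(treat, ctrl)
                rows.append({"compound": cond.compound,
                             "concentration": cond.concentration,
                             "age_day": day, "z": round(res.z, 3),
                             "quality": res.quality})
            except PiclsError as exc:
                rows.append({"compound": cond.compound,
                             "concentration": cond.concentration,
                             "age_day": day, "z": None, "quality": str(exc)})
    zdf = pd.DataFrame(rows)
    zdf.to_csv(OUT / "zfactors.csv", index=False)
    best = zdf[(zdf["compound"] == "rapamycin") & (zdf["age_day"] == 7)]
    if not best.empty:
        click.echo(f"day-7 rapamycin-like vs untreated: Z = "
                   f"{best['z'].iloc[0]:.2f} ({best['quality'].iloc[0]})")
    click.echo(f"wrote qc_report.json and zfactors.csv to {OUT}")


if __name__ == "__main__":
    main()
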