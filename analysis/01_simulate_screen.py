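#!/usr/bin/env python
"""Simulate the default geroprotector screen and write its plate exports.

Produces the inputs every later analysis step consumes: a long-table CSV
of all simulated wells (5 arms x days 1/4/7/14/21 x 12 replicates, plus
triplicate unstained/boiled controls on every plate), the generator's
ground-truth viability table, and growth-phase ODs for the toxicity gate.
"""
from pathlib import Path

import click

from picls.plate_io import write_long_table
from picls.simulate import MeasurementModel, default_screen, simulate_growth, simulate_plate

OUT = Path(__file__).resolve().parent.parent / "results"


@click.command()
@click.option("--seed", type=int, default=1, show_default=True)
@click.option("--n-replicates", type=int, default=12, show_default=True)
def main(seed, n_replicates):
    OUT.mkdir(exist_ok=True)
    design = default_screen(n_replicates=n_replicates)
    measurement = MeasurementModel(cv=0.05)
    records, truth = simulate_plate(design, measurement, seed)
    write_long_table(records, OUT / "plates.csv")
    truth.to_csv(OUT / "ground_truth.csv", index=False)
    growth = simulate_growth(design, measurement, seed + 1)
    growth.to_csv(OUT / "growth.csv", index=False)
    n_plates = len({r.plate_id for r in records})
    click.echo(f"simulated {len(records)} wells on {n_plates} plates "
               f"({len(design.arms)} arms, days {design.age_days}); "
               f"wrote plates.csv, ground_truth.csv, growth.csv to {OUT}")


if __name__ == "__main__":
    main()
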