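#!/usr/bin/env python
"""Classify the simulated cohort into intolerance cases and tolerant controls.

Applies the EMR phenotyping rules (coverage, switches, discontinuations,
on-statin CK flags) and reports the class counts plus agreement with the
generator's planted truth.
"""

import argparse
from pathlib import Path

import pandas as pd

from statintol.config import RulesConfig
from statintol.pipeline import run_phenotype

parser = argparse.ArgumentParser()
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()

paths = run_phenotype(args.out_dir / "cohort", args.out_dir, RulesConfig())
asg = pd.read_csv(paths["assignments"])
truth = pd.read_csv(args.out_dir / "cohort" / "truth.csv")
m = asg.merge(truth, on="patient_id")

for phen in ("gsi", "ldi"):
    counts = asg[phen].value_counts().to_dict()
    agree = (m[phen] == m[f"{phen}_truth"]).mean()
    print(f"{phen.upper()}: {counts}; agreement with planted truth {agree:.1%}")
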