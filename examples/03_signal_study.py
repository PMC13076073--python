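"""Run the full study pipeline: three drug queries x five renal endpoints.

The synthetic database plants elevated renal reporting odds (theta = 8) for
lithium and reduced odds (theta = 0.5, except acute kidney injury) for
semaglutide. The pipeline curates the raw tables, builds one 2x2 table per
(query, endpoint) pair against the whole-database comparator, and prints the
study-shaped results table. Expect SIGNAL on every lithium row, NO_SIGNAL on
every semaglutide row, and mostly not-estimable (NE) co-reporting rows —
co-mentions of two low-prevalence drugs are rare.
"""
import tempfile
from pathlib import Path

from pvsignal import RunConfig, run_pipeline
from pvsignal import study

with tempfile.TemporaryDirectory() as tmp:
    raw = study.write_study_inputs(Path(tmp) / "raw", n_reports=60_000, seed=7)
    config = RunConfig(
        input_dir=raw,
        synonyms_path=raw / "synonyms.csv",
        window=study.WINDOW,
        endpoints_path=raw / "endpoints.json",
        queries=study.study_queries(),
        out_dir=Path(tmp) / "out",
        forest_svg=False,
    )
    rows = run_pipeline(config)
    print((Path(tmp) / "out" / "results.csv").read_text())

print("Each row: query, endpoint, 2x2 cells, ROR with Woolf CI, Fisher p,")
print("PRR, RRR, Yates chi2, IC and IC025, Evans screen, classification.")
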