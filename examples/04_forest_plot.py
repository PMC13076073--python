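"""Export forest-plot data and render the SVG for a small study.

Forest plots show each (query, endpoint) ROR with its 95% CI on a log axis;
the dashed line at ROR = 1 separates elevated from reduced reporting. Rows
with no cases appear as 'NE' annotations without an interval.
"""
import tempfile
from pathlib import Path

from pvsignal import RunConfig, run_pipeline
from pvsignal import study

out_dir = Path("scratch") / "forest_out"
with tempfile.TemporaryDirectory() as tmp:
    raw = study.write_study_inputs(Path(tmp) / "raw", n_reports=40_000, seed=19)
    config = RunConfig(
        input_dir=raw,
        synonyms_path=raw / "synonyms.csv",
        window=study.WINDOW,
        endpoints_path=raw / "endpoints.json",
        queries=study.study_queries(),
        out_dir=out_dir,
        forest_svg=True,
    )
    run_pipeline(config)

print((out_dir / "forest.csv").read_text())
print(f"rendered {out_dir / 'forest.svg'}")
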