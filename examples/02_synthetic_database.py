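"""Generate a synthetic spontaneous-report database and curate it.

The generator plants a known drug-event odds multiplier (theta), clones a
fraction of reports as near-duplicates and corrupts another fraction into
structurally invalid records. Curation then has to undo exactly that
contamination, and the ground truth lets us check it did.
"""
from pvsignal import curate, generate_reports
from pvsignal.simulate import Effect
from pvsignal import study

config = study.default_sim_config(
    n_reports=20_000,
    seed=42,
    effects=[Effect("lithium", "Acute kidney injury", 8.0)],
    duplicate_rate=0.05,
    invalid_rate=0.02,
)
reports, truth = generate_reports(config)
print(f"generated {len(reports)} reports "
      f"({config.n_reports} primaries, {len(truth.duplicate_of)} duplicate clones, "
      f"{len(truth.invalid_ids)} invalid records)")

curated, report = curate(reports, study.default_synonym_map(), study.WINDOW)
print(f"curation kept {report.n_output}, excluded {report.n_excluded_invalid} invalid "
      f"({dict(report.exclusion_reasons)}), removed {report.n_removed_duplicates} duplicates")

kept = {r.report_id for r in curated}
recalled = sum((c in kept) + (s in kept) == 1 for c, s in truth.duplicate_of.items())
print(f"clone groups collapsed to one record: {recalled}/{len(truth.duplicate_of)}")
print("conservation: n_input == n_output + excluded + removed ->",
      report.n_input == report.n_output + report.n_excluded_invalid + report.n_removed_duplicates)
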