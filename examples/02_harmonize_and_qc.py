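"""Parse, complete, harmonize and quality-control a summary-statistics file.

Uses the generated fixture suite: a 200-animal panel and a GWAS table
in a foreign column dialect, plus a deliberately corrupted copy whose
p-values no longer match beta/se.
"""

import tempfile
from pathlib import Path

import ovismap as ov

work = Path(tempfile.mkdtemp())
ov.make_fixture_suite(work, seed=7)

panel = ov.read_plink(work / "panel")
ref, _ = ov.build_reference_table(panel)

raw, parse_log = ov.parse_sumstats(work / "gwas_a.tsv", column_map=ov.GWAS_COLUMN_MAP)
completed = ov.complete_statistics(raw)  # fills se/z/p from whichever was present
study = ov.harmonize(completed, ref, study_key="trait_a")
print(f"parsed {parse_log.n_parsed} rows; harmonization dispositions: {study.log.counts}")
# sign_flipped records had their effective allele on the other side of the
# catalogue orientation; their beta, z and eaf were complemented.

results = ov.run_all_checks(study, ref)
for r in results:
    print(f"  {r.check_name}: {'PASS' if r.passed else 'FAIL'} "
          f"({r.n_flagged} flagged) {dict(list(r.metrics.items())[:2])}")
report = ov.render_report(results, study.log, work / "qc.html", study=study, ref=ref)
print(f"HTML report -> {report}")

# the corrupted file fails stage 3 (p no longer corresponds to beta/se)
raw_bad, _ = ov.parse_sumstats(work / "gwas_bad_p.tsv", column_map=ov.GWAS_COLUMN_MAP)
raw_bad["z"] = raw_bad["beta"] / raw_bad["se"]
bad = ov.harmonize(raw_bad, ref, study_key="bad")
res = ov.check_pz_consistency(bad)
print(f"corrupted study p-z check: {'PASS' if res.passed else 'FAIL'} "
      f"({res.n_flagged} records flagged)")
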