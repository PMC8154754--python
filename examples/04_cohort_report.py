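"""End-to-end validation study on a 15-subject synthetic cohort.

Simulates bilateral dual-echo studies for 10 young and 5 senior subjects,
segments them with simulated readers at target Dice 0.70, fits aT2* and CSA
with the extreme-slice discard rule, and prints the four report tables
(demographics, group comparisons, reader agreement, SNR/CNR).
"""
from vtemri import demo_config, run_pipeline

report = run_pipeline(demo_config(out_dir="scratch_demo", seed=0))

for name, table in report.tables.items():
    print(f"\n=== {name} ===")
    print(table.to_string(index=False))

m = report.manifest
print(f"\n{len(m['outputs'])} output files in {report.out_dir} "
      f"(seed {m['seed']}, config hash {m['config_hash'][:12]}...)")
print("Re-running with the same config and seed reproduces every file "
      "bit for bit; a second call is a no-op.")
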