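"""Simulate a high-throughput plate and reproduce the throughput report.

A 518-specimen cohort (279 morphology-labelled males, 9 amplification
failures, 30 misidentified male labels) is simulated at species melting peaks
79.4 / 77.0 C with 0.15 C well-to-well jitter, classified against those
reference peaks, and summarized as a throughput table.
"""

from meltdiag import CohortSpec, classify_curves, make_cohort, summarize_assay

curves, metadata = make_cohort(CohortSpec(seed=1))
print(f"Simulated {len(curves)} melt curves (65-85 C grid, 0.05 C step)")

refs = {"marginata-like": 79.4, "dolus-like": 77.0}
calls = classify_curves(curves, refs)
report = summarize_assay(calls, metadata)
print()
print(report.to_text())
print(
    "\nEvery non-failed specimen is assigned to a species (no ambiguous"
    " curves) because the 2.4 C peak separation dwarfs the 0.15 C jitter;"
    " the 10.75% male discordance is the simulated morphological"
    " misidentification rate, recovered exactly by the molecular calls."
)
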