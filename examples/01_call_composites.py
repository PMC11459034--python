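"""Call composite mutations in a tiny hand-built cohort.

Two well-known composite cases are planted: a melanoma sample carrying both
BRAF V600E and V600M, and a lung adenocarcinoma carrying EGFR T790M and
L858R.  Each gene accumulates two independent driver hits, so both are
called composite (oncogene rule: >=2 driver-level events in one gene).
"""

import pandas as pd

from compmut import call_composites, composite_prevalence, extract_driver_events, load_cohort
from compmut.io_formats import HotspotCatalog
from compmut.synthetic_data import default_layout

annotations = pd.DataFrame(
    [
        ("BRAF", "oncogene", "7", 140_719_327, 140_924_929),
        ("EGFR", "oncogene", "7", 55_019_017, 55_211_628),
        ("KRAS", "oncogene", "12", 25_205_246, 25_250_929),
        ("PTEN", "tumor_suppressor", "10", 87_863_113, 87_971_930),
    ],
    columns=["symbol", "role", "chromosome", "start", "end"],
)
hotspots = HotspotCatalog.from_pairs(
    [("BRAF", "V600E"), ("BRAF", "V600M"), ("EGFR", "T790M"), ("EGFR", "L858R"), ("KRAS", "G12D")]
)
samples = pd.DataFrame(
    {
        "sample_id": ["MEL-01", "LUAD-02", "LUAD-03"],
        "tumor_type": ["skin", "lung", "lung"],
        "source": "tissue",
    }
)
mutations = pd.DataFrame(
    [
        ("MEL-01", "BRAF", "V600E", "7", 140_753_336, "A", "T"),
        ("MEL-01", "BRAF", "V600M", "7", 140_753_337, "C", "T"),
        ("MEL-01", "KRAS", "G12D", "12", 25_245_350, "C", "T"),
        ("LUAD-02", "EGFR", "T790M", "7", 55_181_378, "C", "T"),
        ("LUAD-02", "EGFR", "L858R", "7", 55_191_822, "T", "G"),
        ("LUAD-03", "KRAS", "G12D", "12", 25_245_350, "C", "T"),
    ],
    columns=["sample_id", "gene", "protein_change", "chromosome", "position", "ref_allele", "alt_allele"],
)
cnvs = pd.DataFrame([("MEL-01", "PTEN", -2)], columns=["sample_id", "gene", "call"])

cohort = load_cohort(
    maf=mutations, cnv=cnvs, annotations=annotations,
    hotspots=hotspots, samples=samples, layout=default_layout(),
)
events = extract_driver_events(cohort)
calls = call_composites(events, cohort.annotations)
prevalence = composite_prevalence(calls, cohort)

print("driver-level events:")
print(events.to_string(index=False))
print("\ncomposite calls (>=2 events for oncogenes, >=3 for tumor suppressors):")
print(calls.to_string(index=False))
print(
    f"\nprevalence: {prevalence.n_composite_samples}/{prevalence.n_samples} samples "
    f"({100 * prevalence.overall:.0f}%) carry a composite mutation"
)
# LUAD-03 has a single KRAS hit and MEL-01's lone PTEN deletion is one of
# three required events for a tumor suppressor, so neither yields a call.
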