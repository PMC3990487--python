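"""Generate a synthetic three-accession TE study and inspect its structure.

The generator draws an exemplar database (DNA transposons plus low- and
high-copy retroelement groups), then allocates genomic reads multinomially
among a gene compartment, a knob compartment and the exemplars in
proportion to copy number x length.
"""

from tedynamics import SimulationConfig, generate_exemplar_db, simulate_genomic_hits

config = SimulationConfig(seed=1, n_dna=200, n_r1=120, n_r2=80, library_size=500_000)
db, truth = generate_exemplar_db(config)

print(f"exemplars: {len(db)}  (groups: {truth.groups.value_counts().to_dict()})")
lengths = db.to_frame().groupby(truth.groups)["length"].mean().round(0)
print(f"mean exemplar length by group (bp): {lengths.to_dict()}")
copies = truth.copies("B73").groupby(truth.groups).median().round(1)
print(f"median true copy number by group: {copies.to_dict()}")

counts = simulate_genomic_hits(db, truth, config, "B73")
print(
    f"B73 library: {counts.total_ute_hits:.0f} TE hits, "
    f"{counts.fgs_hits:.0f} gene hits, {counts.knob_hits:.0f} knob hits "
    f"(sum = {counts.total_ute_hits + counts.fgs_hits + counts.knob_hits:.0f} reads)"
)
# The three totals always sum exactly to the configured library size: reads
# are allocated multinomially, so conservation is exact, not approximate.
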