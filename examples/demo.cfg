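# lncwheat demo configuration: a small synthetic run exercising every stage.
# Any omitted key keeps its default (see src/lncwheat/config.py).

n_coding = 200
n_lncrna = 120
n_contaminant = 30
n_as_loci = 40
n_precursors = 20

# analysis constants (defaults restated here for visibility)
min_orf_nt = 240
min_lncrna_len = 200
contaminant_min_identity = 95
contaminant_min_length = 30
protein_min_identity = 80
protein_min_length = 30
de_alpha = 0.001
de_lfc_min = 2
fpkm_fallback_threshold = 0.5
alignment_min_identity = 90
mature_max_mismatch = 2
expectation_cutoff = 3.0
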