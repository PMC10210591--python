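# Illustrative (NON-authoritative) peptide motif -> wheat subgenome table.
# The published motif compilations for alpha-gliadin subgenome assignment are
# not redistributed here; supply your own table for real data.  The synthetic
# generator plants exactly these motifs, so the default table is internally
# consistent for simulated panels.
motif	subgenome
PQQQVPQ	A
PQQLVPQ	B
PQQSVPQ	D
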