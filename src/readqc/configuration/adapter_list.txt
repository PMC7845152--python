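# Adapter sequences searched for in every read (Adapter Content module).
# Format: <name><TAB><sequence>.  These are the standard 12-mer probes used
# by FastQC-style adapter screening.

Illumina Universal Adapter	AGATCGGAAGAG
Illumina Small RNA 3' Adapter	TGGAATTCTCGG
Illumina Small RNA 5' Adapter	GATCGTCGGACT
Nextera Transposase Sequence	CTGTCTCTTATA
SOLID Small RNA Adapter	CGCCTTGGCCGT
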