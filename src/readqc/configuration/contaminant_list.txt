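# Contaminant screen for the Overrepresented Sequences module.
# Format: <name><TAB><sequence>.  Curated subset of commonly observed
# Illumina library-preparation adapter and primer sequences.

Illumina Single End Adapter 1	GATCGGAAGAGCTCGTATGCCGTCTTCTGCTTG
Illumina Single End Adapter 2	CAAGCAGAAGACGGCATACGAGCTCTTCCGATCT
Illumina Single End PCR Primer 1	AATGATACGGCGACCACCGAGATCTACACTCTTTCCCTACACGACGCTCTTCCGATCT
Illumina Single End Sequencing Primer	ACACTCTTTCCCTACACGACGCTCTTCCGATCT
Illumina Paired End Adapter 1	ACACTCTTTCCCTACACGACGCTCTTCCGATCT
Illumina Paired End Adapter 2	GATCGGAAGAGCGGTTCAGCAGGAATGCCGAG
Illumina Paired End PCR Primer 1	AATGATACGGCGACCACCGAGATCTACACTCTTTCCCTACACGACGCTCTTCCGATCT
Illumina Paired End PCR Primer 2	CAAGCAGAAGACGGCATACGAGATCGGTCTCGGCATTCCTGCTGAACCGCTCTTCCGATCT
Illumina Paired End Sequencing Primer 1	ACACTCTTTCCCTACACGACGCTCTTCCGATCT
Illumina Paired End Sequencing Primer 2	CGGTCTCGGCATTCCTGCTGAACCGCTCTTCCGATCT
Illumina Multiplexing Adapter 1	GATCGGAAGAGCACACGTCT
Illumina Multiplexing Index Sequencing Primer	GATCGGAAGAGCACACGTCTGAACTCCAGTCAC
TruSeq Adapter Index 1	GATCGGAAGAGCACACGTCTGAACTCCAGTCACATCACGATCTCGTATGCCGTCTTCTGCTTG
TruSeq Adapter Index 2	GATCGGAAGAGCACACGTCTGAACTCCAGTCACCGATGTATCTCGTATGCCGTCTTCTGCTTG
TruSeq Adapter Index 3	GATCGGAAGAGCACACGTCTGAACTCCAGTCACTTAGGCATCTCGTATGCCGTCTTCTGCTTG
Nextera Transposase Read 1 Sequence	TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG
Nextera Transposase Read 2 Sequence	GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG
ABI Solid3 Adapter A	CTGCCCCGGGTTCCTCATTCTCT
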