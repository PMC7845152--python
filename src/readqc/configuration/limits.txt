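# Default module thresholds, in FastQC's limits.txt dialect.
# Each line is:  <module-key>  <warn|error|ignore>  <value>
# "warn"/"error" give the threshold at which the module raises that grade
# (comparisons are strict); "ignore 1" disables the module entirely.

duplication	warn	70
duplication	error	50
kmer	warn	2
kmer	error	5
n_content	warn	5
n_content	error	20
overrepresented	warn	0.1
overrepresented	error	1
quality_base_lower	warn	10
quality_base_lower	error	5
quality_base_median	warn	25
quality_base_median	error	20
sequence	warn	10
sequence	error	20
gc_sequence	warn	15
gc_sequence	error	30
quality_sequence	warn	27
quality_sequence	error	20
tile	warn	5
tile	error	10
sequence_length	warn	1
sequence_length	error	1
adapter	warn	5
adapter	error	10

duplication	ignore	0
kmer	ignore	1
n_content	ignore	0
overrepresented	ignore	0
quality_base	ignore	0
sequence	ignore	0
gc_sequence	ignore	0
quality_sequence	ignore	0
tile	ignore	0
sequence_length	ignore	0
adapter	ignore	0
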