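name,copy_number,genome_size,gram
A. vaginae,1,1.43,+
G. vaginalis,2,1.65,+
L. crispatus,4,2.04,+
L. iners,1,1.30,+
P. bivia,1,2.47,-
S. agalactiae,7,2.20,+
S. amnii,1,1.34,-
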