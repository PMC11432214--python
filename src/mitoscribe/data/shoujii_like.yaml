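# Default simulation scenario: a Sericothrips-like rearranged mitogenome
# transcribed from two control-region TIS/TTS pairs per strand plus a third
# initiation site inside the antisense of lrRNA, processed by tRNA-punctuated
# cleavage (mostly 3'->5'), with exonucleolytic degradation and polyA tails.
# Strand strengths reproduce the slight N-over-J transcript excess of the
# real library (about 51.6% N).
name: shoujii_like
annotation: sericothrips_refined
n_transcripts: 5000
seed: 42
end_noise_sd: 1.0
min_length: 20
tis:
  J:
    - {position: 3880, strength: 1.2}    # CR1
    - {position: 9600, strength: 1.6}    # CR2
  N:
    - {position: 4040, strength: 1.0}    # CR1
    - {position: 9620, strength: 0.4}    # CR2
    - {position: 13864, strength: 1.59}  # inside antisense lrRNA
tts:
  J:
    - {position: 3950, read_through: 0.25}  # CR1 repeat region
    - {position: 9550, read_through: 0.70}  # CR2
  N:
    - {position: 3945, read_through: 0.70}  # CR1 repeat region
    - {position: 9650, read_through: 0.25}  # CR2 repeat region
cleavage:
  completion: 0.9
  reverse_fraction: 0.9
degradation:
  fraction: 0.2
  mean_trim: 150
  p_five_prime: 0.5
polya:
  mean: 30
  sd: 10
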