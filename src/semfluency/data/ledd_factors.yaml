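# Levodopa-equivalent dose conversion table.
# Source: the systematic LED review of Tomlinson et al. (2010), Mov Disord 25:2649-2653.
# factor: LED mg per mg of drug. Augmenters add a fraction of the concurrent
# levodopa LED instead of contributing via their own dose.
version: "tomlinson-2010"
factors:
  levodopa: 1.0
  pramipexole: 100.0
  piribedil: 1.0
  ropinirole: 20.0
  rotigotine: 30.0
  selegiline: 10.0
  rasagiline: 100.0
  amantadine: 1.0
  apomorphine: 10.0
  bromocriptine: 10.0
augmenters:
  entacapone: 0.33
  tolcapone: 0.5
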