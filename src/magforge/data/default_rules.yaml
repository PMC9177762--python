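fermentation_rules:
  acetate:
  - - pta
    - ackA
  butyrate:
  - - ptb
    - buk
  - - but
  lactate:
  - - ldh
  methanogenesis:
  - - mcrA
  propionate:
  - - mmdA
    - mutA
    - mce
  succinate:
  - - men
    - fum
    - frd
pathway_markers:
  PPP:
  - K00036
  - K01057
  - K00033
  - K01783
  - K01808
  - K00615
  - K00616
  TCA:
  - K01647
  - K01681
  - K00031
  - K00164
  - K01902
  - K00239
  - K01679
  - K00024
  glycolysis:
  - K00845
  - K01835
  - K00850
  - K01623
  - K01803
  - K00134
  - K00927
  - K01834
  - K01689
  - K00873
pathway_threshold: 0.75
polymer_families:
  cellulose:
  - GH5
  - GH9
  - GH44
  - GH45
  - GH48
  chitin:
  - GH18
  - GH19
  pectin:
  - GH28
  - PL1
  - PL9
  - CE8
  - GH78
  starch:
  - GH13
  - GH57
  - GH97
  - GH77
  xylan:
  - GH10
  - GH11
  - GH8
  - CE1
  - CE2
  - CE4
  xyloglucan:
  - GH16
  - GH74
  - GH31
sugar_markers:
  arabinose: K01804
  fructose: K00847
  fucose: K01818
  galactose: K00849
  glucose_6P: K01810
  mannose: K01809
  rhamnose: K01813
  xylose: K01805
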