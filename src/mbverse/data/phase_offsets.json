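{
 "1:0": [
  0.0
 ],
 "1:1": [
  0.0
 ],
 "2:0": [
  0.0,
  4.002148315014479
 ],
 "2:1": [
  0.0,
  0.0
 ],
 "3:0": [
  0.0,
  4.931766917477967,
  0.4387558731174323
 ],
 "3:1": [
  0.0,
  0.0,
  3.141592653589793
 ],
 "4:0": [
  0.0,
  5.524592462692378,
  2.9567242417741713,
  4.862765925714005
 ],
 "4:1": [
  0.0,
  3.141592653589793,
  0.0,
  0.0
 ],
 "5:0": [
  0.0,
  0.5210128036724209,
  5.102773703840565,
  3.6655492434712484,
  0.0058876600136372
 ],
 "5:1": [
  0.0,
  3.141592653589793,
  0.0,
  0.0,
  0.0
 ],
 "6:0": [
  0.0,
  3.0733196632918025,
  2.209486639918109,
  3.953696705012605,
  2.0227635407287203,
  2.437863529015096
 ],
 "6:1": [
  0.0,
  0.0,
  3.141592653589793,
  0.0,
  3.141592653589793,
  3.141592653589793
 ],
 "7:0": [
  0.0,
  1.0676900245164898,
  2.135376946916386,
  0.06147293247535953,
  1.1291605482531393,
  5.33844257991842,
  3.2645361100293995
 ],
 "7:1": [
  0.0,
  3.141592653589793,
  0.0,
  0.0,
  3.141592653589793,
  3.141592653589793,
  3.141592653589793
 ],
 "8:0": [
  0.0,
  4.218287947380566,
  0.7959704827579883,
  5.672187945094467,
  5.17525621254651,
  5.588365239805959,
  1.7336365335130175,
  2.804680108095412
 ],
 "8:1": [
  0.0,
  0.0,
  0.0,
  3.141592653589793,
  0.0,
  3.141592653589793,
  3.141592653589793,
  0.0
 ],
 "9:0": [
  0.0,
  1.60318356560138,
  2.479029128194202,
  4.573924922564378,
  2.1407265908629527,
  5.024974715172515,
  3.3811755523989255,
  2.9563857976682475,
  1.8042993557520586
 ],
 "9:1": [
  0.0,
  0.0,
  0.0,
  3.141592653589793,
  0.0,
  3.141592653589793,
  0.0,
  0.0,
  3.141592653589793
 ],
 "10:0": [
  0.0,
  3.2450233053488593,
  0.22479923755238337,
  4.709942168035942,
  0.003028983890896342,
  0.6800160872362029,
  5.806466313558746,
  5.715035033310473,
  2.812725712585707,
  3.0463669690401076
 ],
 "10:1": [
  0.0,
  0.0,
  0.0,
  0.0,
  3.141592653589793,
  3.141592653589793,
  0.0,
  3.141592653589793,
  0.0,
  3.141592653589793
 ],
 "11:0": [
  0.0,
  4.571702949734342,
  0.7002396724827663,
  4.829005851593307,
  2.0852810952192296,
  1.8925658835882873,
  1.1152411355231904,
  2.8889254888512834,
  4.073305047943406,
  0.6915439501242213,
  1.4329882871150974
 ],
 "11:1": [
  0.0,
  0.0,
  0.0,
  3.141592653589793,
  3.141592653589793,
  3.141592653589793,
  0.0,
  3.141592653589793,
  3.141592653589793,
  0.0,
  3.141592653589793
 ],
 "12:0": [
  0.0,
  3.6270013816143996,
  2.1058960772605957,
  6.149559418381802,
  0.5685604461147878,
  4.199460499890069,
  6.121402750549674,
  3.772305261756878,
  3.8868874205714525,
  4.153930654074615,
  4.705719095009835,
  6.2172005570405915
 ],
 "12:1": [
  0.0,
  3.141592653589793,
  0.0,
  3.141592653589793,
  0.0,
  0.0,
  3.141592653589793,
  3.141592653589793,
  0.0,
  0.0,
  0.0,
  0.0
 ]
}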