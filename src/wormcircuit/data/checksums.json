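{
 "cri_table.tsv": "8a2174c901af721a37d5ff253eb7e476c2b7e47816786a67a8d7b76228b88c08",
 "seed_neurons.txt": "810bb615a911971ccc80faf2933c7e8304bc4737874f33efdb910a567a431703",
 "circuit_synthetic.json": "3822e85c8e76d1bfaedcf5ac041e1f5e885ab6e03dd8fa060bfcd51ca2ffffb6"
}
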