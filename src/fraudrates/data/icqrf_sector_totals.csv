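sector,inspections,irregularities
wine,159187,44836
milk and dairy products,67413,6701
oils and fats,81790,7883
feed and supplements,36361,5576
eggs,17784,2582
honey,12224,1209
sowing seeds,16061,3738
vegetable preserves,23139,1764
meat,30049,4489
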