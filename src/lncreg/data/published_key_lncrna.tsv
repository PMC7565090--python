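tissue	transcript
adrenal gland	TCONS_00106745
adrenal gland	TCONS_00040537
adrenal gland	TCONS_00006522
adrenal gland	TCONS_00013774
adrenal gland	TCONS_00022218
adrenal gland	TCONS_00048225
adrenal gland	TCONS_00064059
adrenal gland	TCONS_00065193
adrenal gland	TCONS_00065195
adrenal gland	TCONS_00083522
adrenal gland	TCONS_00088984
adrenal gland	TCONS_00126728
adrenal gland	TCONS_00154980
adrenal gland	TCONS_00159584
adrenal gland	TCONS_00171940
adrenal gland	TCONS_00178323
adrenal gland	TCONS_00182439
adrenal gland	TCONS_00186763
adrenal gland	TCONS_00193324
adrenal gland	TCONS_00201789
adrenal gland	TCONS_00219008
hypothalamus	TCONS_00214308
hypothalamus	TCONS_00018896
hypothalamus	TCONS_00028218
hypothalamus	TCONS_00028219
hypothalamus	TCONS_00033000
hypothalamus	TCONS_00061315
hypothalamus	TCONS_00068546
hypothalamus	TCONS_00153695
hypothalamus	TCONS_00157240
hypothalamus	TCONS_00157945
hypothalamus	TCONS_00164540
hypothalamus	TCONS_00169707
hypothalamus	TCONS_00176859
hypothalamus	TCONS_00187047
hypothalamus	TCONS_00198904
liver	TCONS_00056607
liver	TCONS_00079733
liver	TCONS_00090296
liver	TCONS_00096860
liver	TCONS_00111349
liver	TCONS_00159585
liver	TCONS_00185398
liver	TCONS_00190687
muscle	TCONS_00140963
muscle	TCONS_00011978
muscle	TCONS_00028495
muscle	TCONS_00064224
muscle	TCONS_00103343
muscle	TCONS_00116181
muscle	TCONS_00119451
muscle	TCONS_00122105
muscle	TCONS_00135035
muscle	TCONS_00171719
pituitary gland	TCONS_00006521
pituitary gland	TCONS_00012621
pituitary gland	TCONS_00018857
pituitary gland	TCONS_00024003
pituitary gland	TCONS_00029744
pituitary gland	TCONS_00045668
pituitary gland	TCONS_00053912
pituitary gland	TCONS_00056694
pituitary gland	TCONS_00116405
pituitary gland	TCONS_00140488
pituitary gland	TCONS_00142880
pituitary gland	TCONS_00149966
pituitary gland	TCONS_00166200
pituitary gland	TCONS_00184540
pituitary gland	TCONS_00184673
pituitary gland	TCONS_00202748
pituitary gland	TCONS_00222510
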