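wavelength_nm,alpha_CuCl2,alpha_NiCl2,alpha_ink,alpha_water,mus_prime
750,0.00791310728483,0.00182834822251,0.0064,0.0026,1.1675323871
755,0.00810625382161,0.00177823187925,0.00635761589404,0.002575,1.14906152984
760,0.00838868984426,0.00173482781915,0.00631578947368,0.00255,1.13100193333
765,0.0087187538439,0.00169364173735,0.00627450980392,0.002525,1.11334182465
770,0.00908412890708,0.00165383297909,0.00623376623377,0.0025,1.0960698418
775,0.00947822832964,0.00161501800357,0.0061935483871,0.002475,1.07917501686
780,0.00989684180549,0.00157697703285,0.00615384615385,0.00245,1.06264675981
785,0.0103370054919,0.00153956789062,0.00611464968153,0.002425,1.0464748433
790,0.0107965007411,0.00150269126323,0.00607594936709,0.0024,1.03064938793
795,0.0112735940373,0.00146627397758,0.00603773584906,0.002525,1.01516084836
800,0.0117668873459,0.00143025995778,0.006,0.00265,1
805,0.012275225351,0.00139460491004,0.00596273291925,0.002775,0.985157926291
810,0.0127976346302,0.00135927299636,0.00592592592593,0.0029,0.970626006619
815,0.0133332819689,0.00132423464777,0.00588957055215,0.003025,0.956395904726
820,0.0138814447571,0.00128946506859,0.00585365853659,0.00315,0.942459557668
825,0.0144414893376,0.00125494317931,0.00581818181818,0.003275,0.928809165256
830,0.0150128547752,0.00122065084865,0.00578313253012,0.0034,0.915437179971
835,0.0155950404295,0.00118657232251,0.00574850299401,0.003625,0.90233629732
840,0.0161875962677,0.00115269379071,0.00571428571429,0.00385,0.889499446615
845,0.0167901151906,0.00111900305234,0.00568047337278,0.004075,0.87691978216
850,0.0174022268697,0.00108548925344,0.00564705882353,0.0043,0.864590674811
855,0.0180235927359,0.00105214267833,0.00561403508772,0.0046,0.852505703908
860,0.0186539018599,0.00101895458173,0.00558139534884,0.0049,0.840658649548
865,0.0192928675309,0.00098591705213,0.00554913294798,0.0052,0.829043485186
870,0.0199402243909,0.000953022899497,0.00551724137931,0.0055,0.817654370555
875,0.0205957260143,0.000920265562187,0.00548571428571,0.00575,0.806485644881
880,0.0212591428481,0.000887639029083,0.00545454545455,0.006,0.795531820377
885,0.0219302604478,0.000855137774015,0.00542372881356,0.00625,0.78478757602
890,0.0226088779567,0.000822756700129,0.00539325842697,0.0065,0.774247751573
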