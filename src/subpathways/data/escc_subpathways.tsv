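subpathway_id	pathway_name	p_value	fdr
path:00330_1	Arginine and proline metabolism	4.93e-12	4.19e-10
path:00280_1	Valine, leucine and isoleucine degradation	3.12e-07	1.32e-05
path:00410_2	beta-Alanine metabolism	1.19e-06	3.38e-05
path:00260_1	Glycine, serine and threonine metabolism	2.16e-06	4.60e-05
path:00010_1	Glycolysis/Gluconeogenesis	1.45e-05	0.00021
path:00270_1	Cysteine and methionine metabolism	1.59e-05	0.00021
path:00250_2	Alanine, aspartate and glutamate metabolism	1.99e-05	0.00021
path:00250_1	Alanine, aspartate and glutamate metabolism	2.05e-05	0.00021
path:00604_1	Glycosphingolipid biosynthesis - ganglio series	2.80e-05	0.00026
path:00531_2	Glycosaminoglycan degradation	3.50e-05	0.00029
path:00240_1	Pyrimidine metabolism	5.39e-05	0.00041
path:00340_1	Histidine metabolism	7.77e-05	0.00053
path:00052_2	Galactose metabolism	8.18e-05	0.00053
path:00520_1	Amino sugar and nucleotide sugar metabolism	0.00011	0.00067
path:00562_1	Inositol phosphate metabolism	0.00011	0.00067
path:00620_1	Pyruvate metabolism	0.00015	0.00081
path:00640_1	Propanoate metabolism	0.00028	0.0014
path:00230_1	Purine metabolism	0.00031	0.0014
path:00630_1	Glyoxylate and dicarboxylate metabolism	0.00040	0.0017
path:00360_1	Phenylalanine metabolism	0.00041	0.0017
path:00600_1	Sphingolipid metabolism	0.00046	0.0018
path:00532_1	Glycosaminoglycan biosynthesis - chondroitin sulfate	0.00048	0.0018
path:00510_1	N-Glycan biosynthesis	0.00063	0.0023
path:00480_1	Glutathione metabolism	0.00073	0.0025
path:00030_1	Pentose phosphate pathway	0.0010	0.0035
path:00100_4	Steroid biosynthesis	0.0011	0.0038
path:00020_1	Citrate cycle (TCA cycle)	0.0013	0.0042
path:00062_2	Fatty acid elongation	0.0014	0.0043
path:00350_2	Tyrosine metabolism	0.0014	0.0043
path:00561_1	Glycerolipid metabolism	0.0016	0.0046
path:00460_1	Cyanoamino acid metabolism	0.0020	0.0056
path:00053_3	Ascorbate and aldarate metabolism	0.0028	0.0074
path:00770_2	Pantothenate and CoA biosynthesis	0.0031	0.0077
path:00900_2	Terpenoid backbone biosynthesis	0.0031	0.0077
path:00603_1	Glycosphingolipid biosynthesis - globo series	0.0032	0.0077
path:00650_2	Butanoate metabolism	0.0032	0.0077
path:00601_1	Glycosphingolipid biosynthesis - lacto and neolacto series	0.0034	0.0078
path:00760_1	Nicotinate and nicotinamide metabolism	0.0043	0.0094
path:00590_1	Arachidonic acid metabolism	0.0043	0.0094
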